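"""Cumulative DVHs and the scalar dose metrics built on them.

All metrics treat voxels as point samples at their centres (no
partial-volume weighting) and are computed bin-free from the sorted voxel
doses; the DVH curve object carries the exact step curve for plotting. The
DVH is right-continuous and Dx at a step returns the upper dose — Dx is
the *minimum* dose received by the hottest x% of the ROI volume.

Metrics: Dx / Vx, conformity index CI = TV_Dp / V_Dp (fraction of the
prescribed isodose volume that is target), homogeneity index HI = D95/D5,
mean dose, integral dose (body mean dose x body volume in litres), and
D1cc (minimum dose of the hottest 1 cm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, GeometryError, RoiMask

__all__ = [
    "Dvh",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "conformity_index",
    "homogeneity_index",
    "mean_dose",
    "integral_dose",
    "d1cc",
    "dose_at_absolute_volume",
]


@dataclass
class Dvh:
    """Exact cumulative DVH of one ROI.

    ``doses_desc`` holds every ROI voxel dose sorted descending;
    ``thresholds``/``volume_fraction`` give the right-continuous step curve
    (fraction of volume receiving >= threshold), starting at 1.0 and
    dropping to 0 above the maximum dose.
    """

    doses_desc: np.ndarray
    roi_volume_cm3: float
    roi_name: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.doses_desc)

    @property
    def thresholds(self) -> np.ndarray:
        return np.unique(self.doses_desc)

    @property
    def volume_fraction(self) -> np.ndarray:
        thr = self.thresholds
        # fraction receiving >= thr, via position in the ascending sorted array
        asc = self.doses_desc[::-1]
        idx = np.searchsorted(asc, thr, side="left")
        return 1.0 - idx / len(asc)

    @property
    def min_dose(self) -> float:
        return float(self.doses_desc[-1])

    @property
    def max_dose(self) -> float:
        return float(self.doses_desc[0])

    @property
    def mean_dose(self) -> float:
        return float(self.doses_desc.mean())


def _roi_doses(dose: DoseGrid, roi: RoiMask) -> np.ndarray:
    dose.require_same_geometry(roi, "dose grid and ROI mask")
    if roi.n_voxels == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    return dose.values[roi.values]


def compute_dvh(dose: DoseGrid, roi: RoiMask, bin_width: float | None = None) -> Dvh:
    """Exact voxel-counting cumulative DVH (``bin_width`` only coarsens the
    stored curve for plotting; metrics always use the exact doses)."""
    d = np.sort(_roi_doses(dose, roi))[::-1]
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        d = np.floor(d / bin_width) * bin_width
    return Dvh(doses_desc=d, roi_volume_cm3=roi.volume_cm3, roi_name=roi.name)


def dose_at_volume(dvh: Dvh, v_percent: float) -> float:
    """Dx: minimum dose received by the hottest ``v_percent``% of the volume.

    D0 is the maximum dose, D100 the minimum; at a step of the cumulative
    curve the upper dose is returned.
    """
    if not 0.0 <= v_percent <= 100.0:
        raise ValueError(f"volume percentage must be in [0, 100], got {v_percent}")
    if v_percent == 0.0:
        return dvh.max_dose
    m = v_percent / 100.0 * dvh.n_voxels
    k = int(math.ceil(m - 1e-9))
    return float(dvh.doses_desc[min(k, dvh.n_voxels) - 1])


def volume_at_dose(dvh: Dvh, d: float) -> float:
    """Vd: percent of ROI volume receiving at least dose ``d`` (Gy)."""
    asc = dvh.doses_desc[::-1]
    idx = np.searchsorted(asc, d, side="left")
    return float((1.0 - idx / dvh.n_voxels) * 100.0)


def dose_at_absolute_volume(dvh: Dvh, volume_cm3: float) -> float:
    """Minimum dose of the hottest ``volume_cm3`` of the ROI."""
    if volume_cm3 <= 0:
        raise ValueError("volume must be > 0")
    if volume_cm3 > dvh.roi_volume_cm3:
        raise ValueError(
            f"ROI {dvh.roi_name!r} ({dvh.roi_volume_cm3:.3f} cm3) is smaller than "
            f"the requested {volume_cm3} cm3"
        )
    voxel_cm3 = dvh.roi_volume_cm3 / dvh.n_voxels
    k = int(math.ceil(volume_cm3 / voxel_cm3 - 1e-9))
    return float(dvh.doses_desc[min(k, dvh.n_voxels) - 1])


def d1cc(dose: DoseGrid, roi: RoiMask) -> float:
    """Maximum dose covering 1 cm^3 of the ROI (near-maximum dose metric)."""
    return dose_at_absolute_volume(compute_dvh(dose, roi), 1.0)


def conformity_index(dose: DoseGrid, ctv: RoiMask, dp: float) -> float:
    """CI = (target volume covered by the ``dp`` isodose) / (total volume
    covered by the ``dp`` isodose); in [0, 1], 1 is perfectly conformal."""
    dose.require_same_geometry(ctv, "dose grid and CTV mask")
    iso = dose.values >= dp
    v_iso = int(iso.sum())
    if v_iso == 0:
        raise ValueError(f"no voxel receives the prescription dose {dp} Gy; CI undefined")
    tv_iso = int((iso & ctv.values).sum())
    return tv_iso / v_iso


def homogeneity_index(dvh: Dvh) -> float:
    """HI = D95 / D5; 1 for a perfectly homogeneous target dose."""
    d5 = dose_at_volume(dvh, 5.0)
    if d5 <= 0:
        raise ValueError("D5 is zero; HI undefined")
    return dose_at_volume(dvh, 95.0) / d5


def mean_dose(dose: DoseGrid, roi: RoiMask) -> float:
    return float(_roi_doses(dose, roi).mean())


def integral_dose(dose: DoseGrid, body: RoiMask) -> float:
    """Mean body dose times body volume, in Gy·L."""
    volume_l = body.volume_cm3 / 1000.0
    return mean_dose(dose, body) * volume_l
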