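"""Logistic NTCP models over OAR dose metrics, ΔNTCP, and the paired test.

NTCP = 1 / (1 + exp(-S)) with linear predictor
S = intercept + Σ coef_i · metric_i + Σ coef_j · covariate_j,
where each dose term references an ROI name and a metric kind (e.g.
``parotid_contra`` / ``Dmean``). Coefficients are configuration: the
models shipped by :func:`illustrative_models` are clearly-labelled
illustrative logistic models in the style of published head-and-neck
xerostomia/dysphagia NTCP models, not a clinically validated set.

Technique comparisons use the exact two-sided Wilcoxon signed-rank test on
per-patient NTCP pairs (zero differences dropped; all-zero returns p = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "NtcpTerm",
    "NtcpModelSpec",
    "NtcpResult",
    "evaluate_ntcp",
    "delta_ntcp",
    "paired_test",
    "illustrative_models",
    "load_models",
]


@dataclass(frozen=True)
class NtcpTerm:
    roi: str
    metric: str        # e.g. "Dmean"
    coefficient: float  # per Gy


@dataclass
class NtcpModelSpec:
    name: str
    intercept: float
    terms: List[NtcpTerm]
    clinical_covariates: List[Tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"NTCP model {self.name!r} needs at least one dose term")
        for t in self.terms:
            if not math.isfinite(t.coefficient):
                raise ValueError(f"NTCP model {self.name!r}: non-finite coefficient for {t.roi}")


@dataclass
class NtcpResult:
    probability: float
    linear_predictor: float
    contributions: Dict[str, float]


def evaluate_ntcp(
    model: NtcpModelSpec,
    metrics: Mapping[str, Mapping[str, float]],
    covariates: Optional[Mapping[str, float]] = None,
) -> NtcpResult:
    """Evaluate one logistic NTCP model on a plan's dose metrics.

    ``metrics`` maps ROI name -> {metric kind -> value in Gy}. A referenced
    metric that is missing raises with the offending term named.
    """
    s = model.intercept
    contrib: Dict[str, float] = {"intercept": model.intercept}
    for t in model.terms:
        try:
            value = metrics[t.roi][t.metric]
        except KeyError:
            raise KeyError(
                f"NTCP model {model.name!r}: metric {t.metric!r} for ROI {t.roi!r} missing"
            ) from None
        c = t.coefficient * value
        contrib[f"{t.roi}.{t.metric}"] = c
        s += c
    for name, coef in model.clinical_covariates:
        if covariates is None or name not in covariates:
            raise KeyError(f"NTCP model {model.name!r}: covariate {name!r} missing")
        c = coef * covariates[name]
        contrib[name] = c
        s += c
    p = 1.0 / (1.0 + math.exp(-s))
    return NtcpResult(probability=p, linear_predictor=s, contributions=contrib)


def delta_ntcp(reference: NtcpResult, comparator: NtcpResult) -> float:
    """NTCP reduction of ``comparator`` relative to ``reference``, in
    percentage points (positive when the comparator is the better plan)."""
    return (reference.probability - comparator.probability) * 100.0


def paired_test(
    values_a: Sequence[float], values_b: Sequence[float], method: str = "wilcoxon"
) -> float:
    """Two-sided paired significance test on per-patient values.

    Default is the exact Wilcoxon signed-rank test with zero differences
    dropped; ``method="ttest"`` selects the paired t-test instead.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_test requires two equal-length 1-D sequences")
    if len(a) < 5:
        raise ValueError(f"paired_test requires n >= 5 pairs, got {len(a)}")
    if method == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    if method != "wilcoxon":
        raise ValueError(f"unknown method {method!r}")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="exact")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Model configuration


def _spec_from_dict(name: str, d: Mapping) -> NtcpModelSpec:
    terms = [NtcpTerm(t["roi"], t.get("metric", "Dmean"), float(t["coefficient"])) for t in d["terms"]]
    covs = [(c["name"], float(c["coefficient"])) for c in d.get("clinical_covariates", [])]
    return NtcpModelSpec(name=name, intercept=float(d["intercept"]), terms=terms, clinical_covariates=covs)


def load_models(path) -> Dict[str, NtcpModelSpec]:
    """Load NTCP model specs from a YAML mapping of name -> spec."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return {name: _spec_from_dict(name, d) for name, d in raw.items()}


def illustrative_models() -> Dict[str, NtcpModelSpec]:
    """Illustrative logistic NTCP models (NOT clinically validated).

    Shapes follow the published head-and-neck pattern: xerostomia driven by
    parotid/submandibular mean dose, dysphagia by pharyngeal constrictor
    and oral-cavity mean dose; grade >= 2 and >= 3 variants are separate
    models with their own intercepts.
    """
    return {
        "xerostomia_grade2plus": NtcpModelSpec(
            name="xerostomia_grade2plus",
            intercept=-1.5,
            terms=[
                NtcpTerm("parotid_contra", "Dmean", 0.045),
                NtcpTerm("parotid_ipsi", "Dmean", 0.020),
                NtcpTerm("submandibular_contra", "Dmean", 0.010),
            ],
        ),
        "xerostomia_grade3plus": NtcpModelSpec(
            name="xerostomia_grade3plus",
            intercept=-3.2,
            terms=[
                NtcpTerm("parotid_contra", "Dmean", 0.040),
                NtcpTerm("parotid_ipsi", "Dmean", 0.015),
                NtcpTerm("submandibular_contra", "Dmean", 0.010),
            ],
        ),
        "dysphagia_grade2plus": NtcpModelSpec(
            name="dysphagia_grade2plus",
            intercept=-3.0,
            terms=[
                NtcpTerm("pcm_superior", "Dmean", 0.030),
                NtcpTerm("pcm_medius", "Dmean", 0.015),
                NtcpTerm("pcm_inferior", "Dmean", 0.010),
                NtcpTerm("oral_cavity", "Dmean", 0.010),
            ],
        ),
        "dysphagia_grade3plus": NtcpModelSpec(
            name="dysphagia_grade3plus",
            intercept=-5.0,
            terms=[
                NtcpTerm("pcm_superior", "Dmean", 0.025),
                NtcpTerm("pcm_medius", "Dmean", 0.015),
                NtcpTerm("pcm_inferior", "Dmean", 0.010),
                NtcpTerm("oral_cavity", "Dmean", 0.010),
            ],
        ),
    }
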