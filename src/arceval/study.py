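"""End-to-end study orchestration on a synthetic cohort.

`run_study` generates a cohort of synthetic patients and, for each patient
and technique: the plan and its statistics, static or dynamic delivery
time, nominal dose metrics (CI, HI, OAR mean doses, D1/D1cc, integral
dose), NTCP per configured model, and fraction-wise plus course-wise
robust coverage (D98,vwmin / V95 of the voxel-wise minimum over the
28-scenario set). Outputs are per-patient CSVs, cohort summaries with
paired Wilcoxon p-values against the reference technique, and a manifest
recording the config hash and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import dose as dm
from .delivery import dynamic_delivery_time, static_delivery_time
from .machine import MachineModel
from .ntcp import NtcpModelSpec, delta_ntcp, evaluate_ntcp, illustrative_models, paired_test
from .plan import count_energy_up_switches, sequence_layers, validate_plan
from .robustness import accumulate_course, fraction_robustness, generate_scenarios, warp_dose
from .synthetic import (
    AnatomySeriesConfig,
    EngineConfig,
    PhantomConfig,
    make_anatomy_series,
    make_dose,
    make_phantom,
    make_plan,
)

__all__ = ["StudyConfig", "run_study", "report_course_pass"]

logger = logging.getLogger("arceval.study")

OAR_NAMES = [
    "spinal_cord",
    "brainstem",
    "parotid_ipsi",
    "parotid_contra",
    "submandibular_ipsi",
    "submandibular_contra",
    "pcm_superior",
    "pcm_medius",
    "pcm_inferior",
    "oral_cavity",
]


@dataclass
class StudyConfig:
    n_patients: int = 6
    techniques: Sequence[str] = ("impt", "elf_30b", "elf_10b", "elf_30b_rs", "elsa", "sparc")
    reference_technique: str = "impt"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    machine: MachineModel = field(default_factory=MachineModel)
    planning_setup_mm: float = 3.0
    evaluation_setup_mm: float = 1.0
    density_fraction: float = 0.03
    n_weeks: int = 7
    course_pass_threshold_pct: float = 94.0
    out_dir: str = "study_out"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def report_course_pass(d98_vwmin_pct: Dict[str, float], threshold_pct: float = 94.0) -> bool:
    """Clinical course-coverage check: every target strictly above threshold."""
    return all(v > threshold_pct for v in d98_vwmin_pct.values())


def _plan_stats_row(patient: int, technique: str, plan) -> dict:
    seq = sequence_layers(plan)
    return {
        "patient": patient,
        "technique": technique,
        "n_control_points": len(plan.control_points),
        "n_layers": plan.n_layers,
        "n_spots": plan.n_spots,
        "n_up_switches": count_energy_up_switches(seq),
        "n_rs_fields": plan.n_range_shifter_fields,
    }


def _dose_metric_rows(patient, technique, dose_grid, phantom, prescriptions) -> List[dict]:
    rows = []
    for name in ("ctv7000", "ctv5425"):
        dvh = dm.compute_dvh(dose_grid, phantom.masks[name])
        dp = prescriptions[name]
        rows.append(
            {
                "patient": patient,
                "technique": technique,
                "roi": name,
                "CI": dm.conformity_index(dose_grid, phantom.masks[name], 0.95 * dp),
                "HI": dm.homogeneity_index(dvh),
                "Dmean_Gy": dvh.mean_dose,
                "D98_pctDp": dm.dose_at_volume(dvh, 98.0) / dp * 100.0,
                "V95_pct": dm.volume_at_dose(dvh, 0.95 * dp),
            }
        )
    body = phantom.masks["body"]
    rows.append(
        {
            "patient": patient,
            "technique": technique,
            "roi": "body",
            "Dmean_Gy": dm.mean_dose(dose_grid, body),
            "D1cc_Gy": dm.d1cc(dose_grid, body),
            "integral_dose_GyL": dm.integral_dose(dose_grid, body),
        }
    )
    for name in OAR_NAMES:
        roi = phantom.masks[name]
        if roi.n_voxels == 0:
            continue
        dvh = dm.compute_dvh(dose_grid, roi)
        row = {
            "patient": patient,
            "technique": technique,
            "roi": name,
            "Dmean_Gy": dvh.mean_dose,
        }
        if name in ("spinal_cord", "brainstem"):
            row["D1_Gy"] = dm.dose_at_volume(dvh, 1.0)
        rows.append(row)
    return rows


def run_study(config: StudyConfig, ntcp_models: Optional[Dict[str, NtcpModelSpec]] = None) -> dict:
    """Run the full synthetic comparison study; returns the report bundle
    (dict of DataFrames) and writes CSVs plus a manifest to ``out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = ntcp_models or illustrative_models()
    prescriptions = EngineConfig().prescription_gy
    master = np.random.SeedSequence(config.seed)
    patient_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(config.n_patients)]

    plan_rows, time_rows, metric_rows, ntcp_rows, robust_rows = [], [], [], [], []

    for p, pseed in enumerate(patient_seeds):
        stage = "phantom"
        try:
            phantom = make_phantom(config.phantom, seed=pseed)
            targets = [phantom.masks["ctv7000"], phantom.masks["ctv5425"]]
            series = make_anatomy_series(
                phantom, config=AnatomySeriesConfig(n_weeks=config.n_weeks), seed=pseed + 1
            )
            eval_scen = generate_scenarios(config.evaluation_setup_mm, config.density_fraction)
            plan_scen = generate_scenarios(config.planning_setup_mm, config.density_fraction)

            for technique in config.techniques:
                stage = f"plan[{technique}]"
                t_stage = time.time()
                plan = make_plan(technique, seed=pseed + 2)
                violations = validate_plan(plan)
                if violations:
                    raise RuntimeError(f"invalid generated plan: {violations[:3]}")
                plan_rows.append(_plan_stats_row(p, technique, plan))

                stage = f"delivery_time[{technique}]"
                if plan.technique == "dynamic_arc":
                    bd = dynamic_delivery_time(plan, config.machine)
                else:
                    bd = static_delivery_time(plan, sequence_layers(plan), config.machine)
                time_rows.append(
                    {
                        "patient": p,
                        "technique": technique,
                        "delivery_time_min": bd.total_s / 60.0,
                        "time_excl_gantry_min": bd.total_excluding_gantry_s / 60.0,
                        **{k: v for k, v in bd.as_dict().items()},
                    }
                )

                stage = f"dose[{technique}]"
                engine = make_dose(phantom, technique=technique, seed=pseed + 3)
                nominal = engine.dose()
                metric_rows.extend(_dose_metric_rows(p, technique, nominal, phantom, prescriptions))

                stage = f"ntcp[{technique}]"
                oar_metrics = {
                    name: {"Dmean": dm.mean_dose(nominal, phantom.masks[name])}
                    for name in OAR_NAMES
                }
                for mname, model in models.items():
                    res = evaluate_ntcp(model, oar_metrics)
                    ntcp_rows.append(
                        {
                            "patient": p,
                            "technique": technique,
                            "model": mname,
                            "ntcp_pct": res.probability * 100.0,
                        }
                    )

                stage = f"robustness[{technique}]"
                planning_rob = fraction_robustness(engine, plan_scen, targets, prescriptions)
                week_results = []
                per_week_warped = []
                for wk, wk_engine in zip(series.weeks, series.engines(engine)):
                    fr = fraction_robustness(wk_engine, eval_scen, targets, prescriptions)
                    week_results.append((wk.week, fr))
                    warped = [
                        warp_dose(wk_engine.dose(s), wk.deformation) for s in eval_scen
                    ]
                    per_week_warped.append(warped)
                weights = [1.0 / len(series.weeks)] * len(series.weeks)
                course = accumulate_course(per_week_warped, weights, targets, prescriptions)

                for roi in ("ctv7000", "ctv5425"):
                    robust_rows.append(
                        {
                            "patient": p,
                            "technique": technique,
                            "roi": roi,
                            "planning_D98_vwmin_pctDp": planning_rob.target_metrics[roi]["D98_pctDp"],
                            "fraction_D98_vwmin_mean_pctDp": float(
                                np.mean([fr.target_metrics[roi]["D98_pctDp"] for _, fr in week_results])
                            ),
                            "course_D98_vwmin_pctDp": course.target_metrics[roi]["D98_pctDp"],
                            "course_V95_pct": course.target_metrics[roi]["V95_pct"],
                        }
                    )
                logger.info(
                    "patient %d technique %s done in %.1f s", p, technique, time.time() - t_stage
                )
        except Exception as exc:
            raise RuntimeError(f"study failed at stage {stage!r} for patient {p}") from exc

    bundle = {
        "plan_stats": pd.DataFrame(plan_rows),
        "delivery_times": pd.DataFrame(time_rows),
        "dose_metrics": pd.DataFrame(metric_rows),
        "ntcp": pd.DataFrame(ntcp_rows),
        "robustness": pd.DataFrame(robust_rows),
    }

    # cohort NTCP comparison vs the reference technique
    ntcp = bundle["ntcp"]
    comp_rows = []
    ref = config.reference_technique
    if ref in set(config.techniques) and config.n_patients >= 5:
        for technique in config.techniques:
            if technique == ref:
                continue
            for mname in ntcp["model"].unique():
                a = ntcp.query("technique == @ref and model == @mname").sort_values("patient")["ntcp_pct"]
                b = ntcp.query("technique == @technique and model == @mname").sort_values("patient")["ntcp_pct"]
                comp_rows.append(
                    {
                        "technique": technique,
                        "model": mname,
                        "mean_delta_ntcp_pct": float(a.mean() - b.mean()),
                        "wilcoxon_p": paired_test(a.to_numpy(), b.to_numpy()),
                    }
                )
    bundle["ntcp_comparison"] = pd.DataFrame(comp_rows)

    # course-wise pass per patient/technique
    rob = bundle["robustness"]
    pass_rows = []
    for (p, technique), grp in rob.groupby(["patient", "technique"]):
        d98 = dict(zip(grp["roi"], grp["course_D98_vwmin_pctDp"]))
        pass_rows.append(
            {
                "patient": p,
                "technique": technique,
                "course_pass": report_course_pass(d98, config.course_pass_threshold_pct),
            }
        )
    bundle["course_pass"] = pd.DataFrame(pass_rows)

    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False)
        if not df.empty and {"technique"}.issubset(df.columns):
            num = df.select_dtypes("number").columns.difference(["patient"])
            if len(num):
                summary = df.groupby("technique")[list(num)].agg(["mean", "std"])
                summary.to_csv(out / f"{name}_cohort.csv")
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "patient_seeds": patient_seeds,
        "runtime_s": time.time() - t0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
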