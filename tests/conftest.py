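"""Shared fixtures.

The heavy session fixtures run many reduced-size synthetic cohorts through
the full attack battery; they are computed once and shared by the
effect-recovery, null-calibration and type-I tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from connres.attack_resilience import run_attack_battery
from connres.core import ModulePartition
from connres.hub_analysis import build_pc_table, rank_nodes_by_control_pc
from connres.io import subjects_to_frame
from connres.stats_report import build_report, subsample_balance_check
from connres.synthetic_cohort import CohortSpec, build_cohort

#: reduced study conditions for the simulation suites: 20 patients,
#: 10 controls, 30 attacks on 60-node / 8-module networks
REDUCED = dict(
    n_patients=20,
    n_controls=10,
    n_nodes=60,
    n_modules=8,
    lesion_count=30,
    hub_fraction=0.15,
)

N_SEEDS = 20
EFFECT_SEEDS = tuple(range(N_SEEDS))
NULL_SEEDS = tuple(range(100, 100 + N_SEEDS))


def reduced_spec(seed: int, **overrides) -> CohortSpec:
    kwargs = {**REDUCED, **overrides}
    return CohortSpec(seed=seed, **kwargs)


def _run_one(spec: CohortSpec, with_report: bool) -> dict:
    """Cohort -> battery -> PC table -> per-seed summaries."""
    cohort = build_cohort(spec)
    battery = run_attack_battery(cohort)
    out = battery.outcomes
    pat = out[(out["group"] == "patient") & ~out["excluded"]]
    patient_mean = pat.groupby("metric")["r_norm"].mean().to_dict()
    ctrl = out[(out["group"] == "control") & ~out["excluded"]]

    pc = build_pc_table(cohort)
    top, bottom = rank_nodes_by_control_pc(pc)
    pat_pc = pc[pc["group"] == "patient"]
    ctl_pc = pc[(pc["group"] == "control") & (pc["timepoint"] == "TP1")]

    def _mean(sub: pd.DataFrame, nodes) -> float:
        return float(sub[sub["node_id"].isin(nodes)]["pc"].mean())

    summary = {
        "seed": spec.seed,
        "patient_mean_rnorm": patient_mean,
        "control_mean_rnorm": float(ctrl["r_norm"].mean()),
        "hub_pc_diff": _mean(pat_pc, top) - _mean(ctl_pc, top),
        "anti_hub_pc_diff": _mean(pat_pc, bottom) - _mean(ctl_pc, bottom),
        "mean_pc_diff": float(pat_pc["pc"].mean() - ctl_pc["pc"].mean()),
        "mean_pc_control_sem": float(
            ctl_pc.groupby("subject_id")["pc"].mean().sem()
        ),
    }
    if with_report:
        subjects = subjects_to_frame(cohort.subjects)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = build_report(out, pc, subjects)
            eg = out[
                (out["metric"] == "global_efficiency") & ~out["excluded"]
            ]
            balance = subsample_balance_check(
                eg[eg["group"] == "patient"],
                eg[eg["group"] == "control"],
                n_draw=18,
                reps=4,
                seed=spec.seed,
            )
        summary["contrast_table"] = pd.DataFrame(report["contrast_table"])
        summary["balance_estimates"] = balance["estimate"].tolist()
    return summary


@pytest.fixture(scope="session")
def effect_runs() -> list[dict]:
    """Cohorts with hub de-concentration injected in patients only."""
    return [_run_one(reduced_spec(seed), with_report=False)
            for seed in EFFECT_SEEDS]


@pytest.fixture(scope="session")
def null_runs() -> list[dict]:
    """Cohorts with identical generator parameters in both groups."""
    return [
        _run_one(
            reduced_spec(seed, hub_redistribution_patient=0.0),
            with_report=True,
        )
        for seed in NULL_SEEDS
    ]


@pytest.fixture(scope="session")
def exchangeable_null_runs() -> list[dict]:
    """Fully exchangeable groups: identical parameters and no primary
    lesions, so patient and control outcomes share one distribution."""
    return [
        _run_one(
            reduced_spec(
                seed,
                hub_redistribution_patient=0.0,
                include_primary_lesions=False,
            ),
            with_report=False,
        )
        for seed in NULL_SEEDS
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """One tiny effect cohort for structural and report tests."""
    return build_cohort(
        CohortSpec(
            n_patients=6,
            n_controls=4,
            n_nodes=40,
            n_modules=5,
            lesion_count=12,
            hub_fraction=0.15,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_battery(small_cohort):
    return run_attack_battery(small_cohort)


@pytest.fixture(scope="session")
def small_pc_table(small_cohort):
    return build_pc_table(small_cohort)


@pytest.fixture()
def toy_partition() -> ModulePartition:
    return ModulePartition(
        node_ids=tuple("abcdef"), module_ids=np.array([0, 0, 0, 1, 1, 1])
    )
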