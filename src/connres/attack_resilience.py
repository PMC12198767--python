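"""Virtual strokes by node deletion and the normalized resilience statistic.

An attack deletes the regions of a lesion set from a subject's weighted
connectome; the whole matrix is then re-thresholded, re-binarized over the
density grid, and each metric's AUC is recomputed. For a metric M,

    R(M)      = M_pre - M_post
    R_norm(M) = 1 - R_obs(M) / mean(R_control(M))

so controls average exactly 0 by construction and an attack that causes no
damage scores 1. The control reference is the control group at its first
timepoint. Normalization is pooled by default (the denominator is the grand
mean control R for that metric); a per-attack variant (denominator = mean
control R for the same lesion mask) is available. The control-mean-zero
identity holds under both, but per-attack denominators can fall within
noise of zero for weakly damaging masks, which makes the ratio unstable.

An attack is skipped for a subject when its region set lies entirely inside
the regions that subject has already lost (signal dropout or the primary
stroke); partial overlaps proceed on the remaining regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ModulePartition, WeightedConnectome
from .graph_core import DEFAULT_GRID, connectome_metric_profile, positive_threshold
from .lesion_mapping import LesionRegionSet
from .synthetic_cohort import SyntheticCohort

__all__ = [
    "AttackApplication",
    "BatteryResult",
    "NormalizationUndefinedError",
    "apply_attack",
    "resilience_raw",
    "resilience_norm",
    "run_attack_battery",
]

BATTERY_METRICS = ("global_efficiency", "modularity", "clustering")


class NormalizationUndefinedError(ValueError):
    """Raised when the control denominator is numerically indistinguishable
    from zero."""


@dataclass(frozen=True)
class AttackApplication:
    """Result of applying one attack to one connectome."""

    connectome: WeightedConnectome
    removed: frozenset[str]  # regions actually deleted now
    already_absent: frozenset[str]  # requested but previously removed

    @property
    def effective(self) -> bool:
        return bool(self.removed)


def apply_attack(
    conn: WeightedConnectome, attack: LesionRegionSet | Iterable[str]
) -> AttackApplication:
    """Delete the attack's regions from the connectome (ledger reason
    ``attack``).

    Regions already removed upstream are ignored and reported. An attack
    whose regions are all already absent returns the connectome unchanged.
    """
    regions = set(attack.regions if isinstance(attack, LesionRegionSet) else attack)
    present = regions & set(conn.node_ids)
    absent = regions - present
    unknown = absent - conn.removed_ids
    if unknown:
        raise KeyError(f"attack names unknown regions: {sorted(unknown)}")
    if not present:
        return AttackApplication(conn, frozenset(), frozenset(absent))
    out = conn.drop_nodes(present, reason="attack")
    return AttackApplication(out, frozenset(present), frozenset(absent))


def resilience_raw(m_pre: float, m_post: float) -> float:
    """R(M) = M_pre - M_post; positive when the attack degraded the metric."""
    if not (np.isfinite(m_pre) and np.isfinite(m_post)):
        raise ValueError("m_pre and m_post must be finite")
    return float(m_pre) - float(m_post)


def resilience_norm(
    r_obs: float, control_rs: Sequence[float], eps: float = 1e-9
) -> float:
    """R_norm = 1 - r_obs / mean(control_rs); larger means more resilient."""
    control_rs = np.asarray(control_rs, dtype=float)
    if control_rs.size == 0:
        raise ValueError("control_rs must be non-empty")
    denom = float(control_rs.mean())
    if abs(denom) <= eps:
        raise NormalizationUndefinedError(
            f"mean control R = {denom:.3e} is within eps={eps:.1e} of zero"
        )
    return 1.0 - float(r_obs) / denom


@dataclass(frozen=True)
class BatteryResult:
    """Long-format attack outcomes plus the skip log and denominators.

    ``outcomes`` has one row per subject x timepoint x mask x metric with
    columns ``m_pre, m_post, r_raw, r_norm, excluded``; ``skips`` one row
    per skipped (subject, timepoint, mask); ``denominators`` the control
    reference means actually used.
    """

    outcomes: pd.DataFrame
    skips: pd.DataFrame
    denominators: pd.DataFrame
    normalization: str
    control_timepoint: str


def _iter_units(
    connectomes: Mapping[tuple[str, str], WeightedConnectome],
    groups: Mapping[str, str],
    control_timepoint: str,
    include_control_other_tps: bool,
):
    for (sid, tp), conn in connectomes.items():
        group = groups[sid]
        if (
            group == "control"
            and tp != control_timepoint
            and not include_control_other_tps
        ):
            continue
        yield sid, tp, group, conn


def run_attack_battery(
    cohort_or_connectomes: SyntheticCohort | Mapping[tuple[str, str], WeightedConnectome],
    lesion_library: Sequence[LesionRegionSet] | None = None,
    partition: ModulePartition | None = None,
    groups: Mapping[str, str] | None = None,
    normalization: str = "pooled",
    grid: Sequence[float] = DEFAULT_GRID,
    metrics: Sequence[str] = BATTERY_METRICS,
    control_timepoint: str = "TP1",
    include_control_other_tps: bool = False,
    eps: float = 1e-9,
) -> BatteryResult:
    """Run every attack of the library on every subject-timepoint matrix.

    Pre-attack AUC metrics are computed once per subject-timepoint; each
    non-skipped attack recomputes them on the reduced matrix. Raw
    resiliences are then normalized against the control group at
    ``control_timepoint`` (controls' other timepoints are excluded from the
    analysis by default, mirroring the control test-retest convention).
    Denominators within ``eps`` of zero mark the affected outcomes
    ``excluded`` with ``r_norm`` left missing.
    """
    if isinstance(cohort_or_connectomes, SyntheticCohort):
        cohort = cohort_or_connectomes
        connectomes = cohort.connectomes
        lesion_library = (
            lesion_library if lesion_library is not None else cohort.lesion_library
        )
        partition = partition if partition is not None else cohort.partition
        groups = {rec.subject_id: rec.group for rec in cohort.subjects}
    else:
        connectomes = cohort_or_connectomes
        if lesion_library is None or partition is None or groups is None:
            raise ValueError(
                "lesion_library, partition and groups are required when not "
                "passing a SyntheticCohort"
            )
    if normalization not in ("per-attack", "pooled"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    if not any(g == "control" for g in groups.values()):
        raise ValueError("no control subjects: normalization reference missing")

    rows: list[dict] = []
    skips: list[dict] = []
    for sid, tp, group, conn in _iter_units(
        connectomes, groups, control_timepoint, include_control_other_tps
    ):
        conn_pos = positive_threshold(conn)
        pre = connectome_metric_profile(
            conn_pos, partition, grid, metrics=metrics
        )["auc"]
        removed = conn.removed_ids
        for mask in lesion_library:
            if mask.regions <= removed:
                skips.append(
                    {
                        "subject_id": sid,
                        "timepoint": tp,
                        "mask_id": mask.mask_id,
                        "reason": "attack inside already-removed regions",
                    }
                )
                continue
            try:
                app = apply_attack(conn_pos, mask)
                post = connectome_metric_profile(
                    app.connectome, partition, grid, metrics=metrics
                )["auc"]
            except ValueError as exc:  # e.g. post-attack graph too small
                warnings.warn(
                    f"attack {mask.mask_id} failed for {sid}/{tp}: {exc}",
                    stacklevel=2,
                )
                skips.append(
                    {
                        "subject_id": sid,
                        "timepoint": tp,
                        "mask_id": mask.mask_id,
                        "reason": f"metric failure: {exc}",
                    }
                )
                continue
            for m in metrics:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "timepoint": tp,
                        "mask_id": mask.mask_id,
                        "n_removed": len(app.removed),
                        "metric": m,
                        "m_pre": pre[m],
                        "m_post": post[m],
                        "r_raw": resilience_raw(pre[m], post[m]),
                    }
                )

    outcomes = pd.DataFrame(rows)
    skips_df = pd.DataFrame(
        skips, columns=["subject_id", "timepoint", "mask_id", "reason"]
    )
    if outcomes.empty:
        raise ValueError("attack battery produced no outcomes")

    ctrl = outcomes[
        (outcomes["group"] == "control")
        & (outcomes["timepoint"] == control_timepoint)
    ]
    if normalization == "per-attack":
        denom = (
            ctrl.groupby(["mask_id", "metric"])["r_raw"]
            .mean()
            .rename("denominator")
            .reset_index()
        )
        outcomes = outcomes.merge(denom, on=["mask_id", "metric"], how="left")
    else:
        denom = (
            ctrl.groupby("metric")["r_raw"].mean().rename("denominator").reset_index()
        )
        outcomes = outcomes.merge(denom, on="metric", how="left")

    outcomes["excluded"] = (
        outcomes["denominator"].isna() | (outcomes["denominator"].abs() <= eps)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        outcomes["r_norm"] = 1.0 - outcomes["r_raw"] / outcomes["denominator"]
    outcomes.loc[outcomes["excluded"], "r_norm"] = np.nan

    return BatteryResult(
        outcomes=outcomes,
        skips=skips_df,
        denominators=denom,
        normalization=normalization,
        control_timepoint=control_timepoint,
    )
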