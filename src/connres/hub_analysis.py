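"""Nodal participation-coefficient (PC) analysis: hubs, anti-hubs, fits.

Per subject and timepoint, each node's PC is summarized by its AUC over the
proportional-threshold density grid (the same threshold-free convention
used for the whole-brain metrics; a single-density mode is available).
Hubs are the k nodes with the highest control-group mean PC at the control
reference timepoint; anti-hubs the k lowest. Group comparisons, Spearman
correlations with resilience, and an exponentiated-Weibull fit to the PC
distribution (whose fitted skewness summarizes the redistribution) follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .core import ModulePartition, WeightedConnectome
from .graph_core import (
    DEFAULT_GRID,
    connectome_metric_profile,
    positive_threshold,
)
from .synthetic_cohort import SyntheticCohort

__all__ = [
    "build_pc_table",
    "rank_nodes_by_control_pc",
    "spearman_corr",
    "ExponentiatedWeibullFit",
    "fit_exponentiated_weibull",
    "pc_group_summaries",
]


def build_pc_table(
    cohort_or_connectomes: SyntheticCohort | Mapping[tuple[str, str], WeightedConnectome],
    partition: ModulePartition | None = None,
    groups: Mapping[str, str] | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    mode: str = "auc",
    density: float | None = None,
) -> pd.DataFrame:
    """Long table of nodal PC: one row per (subject, timepoint, node).

    ``mode="auc"`` (default) reports the AUC of PC over the density grid;
    ``mode="density"`` evaluates PC at the single density ``density``.
    """
    if isinstance(cohort_or_connectomes, SyntheticCohort):
        cohort = cohort_or_connectomes
        connectomes = cohort.connectomes
        partition = partition if partition is not None else cohort.partition
        groups = {rec.subject_id: rec.group for rec in cohort.subjects}
    else:
        connectomes = cohort_or_connectomes
        if partition is None or groups is None:
            raise ValueError("partition and groups required")
    if mode == "density":
        if density is None:
            raise ValueError("mode='density' requires a density value")
        grid_used: tuple[float, ...] = (float(density),)
    elif mode == "auc":
        grid_used = tuple(grid)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for (sid, tp), conn in connectomes.items():
        prof = connectome_metric_profile(
            positive_threshold(conn), partition, grid_used, metrics=(), nodal_pc=True
        )
        if mode == "auc":
            values = prof["nodal_pc_auc"]
        else:
            values = dict(zip(conn.node_ids, prof["nodal_pc_curves"][:, 0]))
        for nid, pc in values.items():
            rows.append(
                {
                    "subject_id": sid,
                    "group": groups[sid],
                    "timepoint": tp,
                    "node_id": nid,
                    "pc": float(pc),
                }
            )
    return pd.DataFrame(rows)


def rank_nodes_by_control_pc(
    table: pd.DataFrame,
    k: int = 10,
    control_timepoint: str = "TP1",
) -> tuple[list[str], list[str]]:
    """The k highest- and k lowest-PC nodes by control mean at the reference
    timepoint.

    Ranking is a deterministic function of the control rows only; ties are
    broken by node id.
    """
    ctrl = table[
        (table["group"] == "control") & (table["timepoint"] == control_timepoint)
    ]
    if ctrl.empty:
        raise ValueError("no control rows at the reference timepoint")
    means = ctrl.groupby("node_id")["pc"].mean()
    if k > len(means):
        raise ValueError(f"k={k} exceeds node count {len(means)}")
    ranked = means.reset_index().sort_values(
        ["pc", "node_id"], ascending=[False, True], kind="mergesort"
    )["node_id"].tolist()
    top = ranked[:k]
    bottom = sorted(ranked[-k:], key=lambda nid: (means[nid], nid))
    return top, bottom


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Raises on length mismatch, fewer than 3 pairs, or a constant argument
    (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = st.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class ExponentiatedWeibullFit:
    """MLE of the exponentiated Weibull (location fixed at 0).

    ``shape_a`` is the exponentiation shape, ``shape_c`` the Weibull shape.
    ``skewness`` is the fitted distribution's third standardized moment (a
    property of the fitted curve, not of the sample).
    """

    shape_a: float
    shape_c: float
    scale: float
    skewness: float
    log_likelihood: float
    converged: bool


def fit_exponentiated_weibull(
    pc_values: Sequence[float], min_n: int = 30
) -> ExponentiatedWeibullFit:
    """Fit an exponentiated Weibull to a sample of nodal PC values by MLE."""
    x = np.asarray(pc_values, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} values, got {len(x)}")
    if not np.all((x > 0.0) & np.isfinite(x)):
        raise ValueError("PC values must be finite and > 0")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (constant) sample")
    a, c, loc, scale = st.exponweib.fit(x, floc=0.0)
    ll = float(np.sum(st.exponweib.logpdf(x, a, c, loc=0.0, scale=scale)))
    skew = float(st.exponweib.stats(a, c, loc=0.0, scale=scale, moments="s"))
    converged = np.isfinite(ll) and np.isfinite(skew)
    return ExponentiatedWeibullFit(
        shape_a=float(a),
        shape_c=float(c),
        scale=float(scale),
        skewness=skew,
        log_likelihood=ll,
        converged=bool(converged),
    )


def pc_group_summaries(
    table: pd.DataFrame,
    top_nodes: Sequence[str],
    bottom_nodes: Sequence[str],
) -> pd.DataFrame:
    """Mean (and SEM) PC of hubs, anti-hubs and all nodes per group x
    timepoint."""
    pieces = []
    sets = {
        "hub": set(top_nodes),
        "anti_hub": set(bottom_nodes),
        "all": set(table["node_id"].unique()),
    }
    for name, nodes in sets.items():
        sub = table[table["node_id"].isin(nodes)]
        grp = sub.groupby(["group", "timepoint"])["pc"].agg(["mean", "sem", "count"])
        grp = grp.reset_index()
        grp.insert(0, "node_set", name)
        pieces.append(grp)
    out = pd.concat(pieces, ignore_index=True)
    if (out["count"] == 0).any():
        raise ValueError("empty group x timepoint cell in PC summary")
    return out
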