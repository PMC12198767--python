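"""Group-level statistics and report assembly.

Resilience outcomes are repeated measures: one row per subject, timepoint
and attack. Group comparisons use linear mixed-effects models with a single
random intercept per subject (REML, via statsmodels); the four design cells
are control TP1 and patient TP1/TP2/TP3, and pairwise cell contrasts are
Wald z-tests corrected with Benjamini-Hochberg FDR across the full contrast
table of the report. A subsample balance check re-fits the group model on
random patient subsets matched in size to the control group. Lesion-
location effects use a classical one-way ANOVA with Bonferroni-corrected
pairwise comparisons after averaging outcomes across timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "fit_mixed_model",
    "bh_fdr",
    "subsample_balance_check",
    "AnovaResult",
    "anova_by_location",
    "build_report",
    "validate_report",
    "attach_cells",
]

RESILIENCE_METRICS = ("global_efficiency", "modularity", "clustering")


@dataclass(frozen=True)
class ModelSpec:
    """Mixed-model contract: response, fixed effects, random intercept and
    the pairwise contrasts to report."""

    response: str
    fixed_effects: tuple[str, ...]
    random_intercept: str = "subject_id"
    contrasts: tuple[tuple[str, str, str], ...] = ()  # (column, level_a, level_b)

    def validate(self, table: pd.DataFrame) -> None:
        missing = [
            c
            for c in (self.response, *self.fixed_effects, self.random_intercept)
            if c not in table.columns
        ]
        if missing:
            raise ValueError(f"columns missing from table: {missing}")
        if table[self.response].isna().any():
            raise ValueError(f"missing values in response {self.response!r}")


@dataclass(frozen=True)
class MixedModelResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    contrasts: pd.DataFrame
    converged: bool
    n_obs: int
    n_groups: int

    def coef(self, name_contains: str) -> float:
        hits = [n for n in self.params.index if name_contains in n]
        if len(hits) != 1:
            raise KeyError(
                f"{name_contains!r} matches {len(hits)} coefficients: {hits}"
            )
        return float(self.params[hits[0]])


def _formula_terms(table: pd.DataFrame, columns: Sequence[str]) -> list[str]:
    terms = []
    for col in columns:
        if table[col].dtype == object or isinstance(
            table[col].dtype, pd.CategoricalDtype
        ):
            terms.append(f"C({col})")
        else:
            terms.append(col)
    return terms


def _check_design_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    import scipy.linalg

    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, _, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        collinear = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"singular design; collinear columns: {collinear}")


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """Linear mixed model with a random intercept per subject (REML).

    Contrast rows are Wald z-tests on fixed-effect differences, emitted with
    raw p-values so the caller can apply FDR across whatever family it
    reports.
    """
    spec.validate(table)
    groups_col = table[spec.random_intercept]
    if table.groupby(spec.random_intercept).ngroups < 2:
        raise ValueError("need at least 2 subjects")
    terms = _formula_terms(table, spec.fixed_effects)
    formula = f"{spec.response} ~ {' + '.join(terms) if terms else '1'}"

    model = smf.mixedlm(formula, table, groups=groups_col)
    _check_design_rank(model.exog, model.exog_names)
    zero_response = float(np.ptp(table[spec.response].to_numpy())) == 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError):
            if zero_response:
                k = len(model.exog_names)
                zeros = pd.Series(np.zeros(k), index=model.exog_names)
                return MixedModelResult(
                    params=zeros,
                    bse=zeros.copy(),
                    pvalues=pd.Series(np.ones(k), index=model.exog_names),
                    conf_int=pd.DataFrame(
                        np.zeros((k, 2)), index=model.exog_names, columns=[0, 1]
                    ),
                    contrasts=pd.DataFrame(
                        columns=["contrast", "estimate", "se", "pvalue"]
                    ),
                    converged=True,
                    n_obs=len(table),
                    n_groups=table.groupby(spec.random_intercept).ngroups,
                )
            raise

    fe_names = list(model.exog_names)
    fe = res.params[fe_names]
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)],
        index=fe_names,
        columns=fe_names,
    )

    contrast_rows = []
    for col, a, b in spec.contrasts:
        L = pd.Series(0.0, index=fe_names)
        for lvl, sign in ((a, 1.0), (b, -1.0)):
            name = f"C({col})[T.{lvl}]"
            if name in L.index:
                L[name] += sign
            # reference level contributes 0
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        if se == 0.0:
            z, p = np.nan, np.nan
        else:
            z = est / se
            p = 2.0 * st.norm.sf(abs(z))
        contrast_rows.append(
            {
                "contrast": f"{col}: {a} - {b}",
                "estimate": est,
                "se": se,
                "pvalue": p,
            }
        )

    return MixedModelResult(
        params=fe,
        bse=res.bse[fe_names],
        pvalues=res.pvalues[fe_names],
        conf_int=res.conf_int().loc[fe_names],
        contrasts=pd.DataFrame(
            contrast_rows, columns=["contrast", "estimate", "se", "pvalue"]
        ),
        converged=bool(res.converged),
        n_obs=len(table),
        n_groups=table.groupby(spec.random_intercept).ngroups,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_cells(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Add the 4-level design cell (CTRL_TP1, P_TP1, P_TP2, P_TP3)."""
    out = outcomes.copy()
    prefix = out["group"].map({"control": "CTRL", "patient": "P"})
    out["cell"] = prefix + "_" + out["timepoint"].astype(str)
    return out


def subsample_balance_check(
    patient_table: pd.DataFrame,
    control_table: pd.DataFrame,
    n_draw: int = 18,
    reps: int = 4,
    seed: int = 0,
    response: str = "r_norm",
) -> pd.DataFrame:
    """Re-fit the group model on random patient subsets of control-group size.

    Each replicate draws ``n_draw`` patients without replacement, pools them
    with all controls, and fits ``response ~ group`` with a random intercept
    per subject. Deterministic under ``seed``.
    """
    patients = sorted(patient_table["subject_id"].unique())
    if n_draw > len(patients):
        raise ValueError(f"n_draw={n_draw} exceeds patient count {len(patients)}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        drawn = sorted(rng.choice(patients, size=n_draw, replace=False).tolist())
        sub = pd.concat(
            [
                patient_table[patient_table["subject_id"].isin(drawn)],
                control_table,
            ],
            ignore_index=True,
        )
        spec = ModelSpec(
            response=response,
            fixed_effects=("group",),
            contrasts=(("group", "patient", "control"),),
        )
        res = fit_mixed_model(sub.dropna(subset=[response]), spec)
        row = res.contrasts.iloc[0]
        rows.append(
            {
                "replicate": rep + 1,
                "n_patients": n_draw,
                "estimate": row["estimate"],
                "se": row["se"],
                "pvalue": row["pvalue"],
                "patient_ids": ",".join(drawn),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    pvalue: float
    df_between: int
    df_within: int
    group_means: pd.DataFrame
    pairwise: pd.DataFrame
    excluded_groups: tuple[str, ...] = ()


def anova_by_location(
    outcomes: pd.DataFrame,
    subjects: pd.DataFrame,
    response: str = "r_norm",
    unit: str = "subject_mask",
) -> AnovaResult:
    """One-way ANOVA of resilience across primary-lesion locations.

    Outcomes are first averaged across timepoints within each analysis unit
    (``subject_mask``: one value per patient x attack; ``subject``: one per
    patient), then compared across locations with a classical F test and
    Bonferroni-corrected pairwise t-tests. Locations with fewer than 2 units
    are excluded with a warning.
    """
    if "lesion_location" not in subjects.columns:
        raise ValueError("subjects table lacks lesion_location")
    pats = outcomes[outcomes["group"] == "patient"].dropna(subset=[response])
    merged = pats.merge(
        subjects[["subject_id", "lesion_location"]], on="subject_id", how="left"
    )
    keys = {
        "subject_mask": ["subject_id", "mask_id", "lesion_location"],
        "subject": ["subject_id", "lesion_location"],
    }
    if unit not in keys:
        raise ValueError(f"unknown unit {unit!r}")
    agg = merged.groupby(keys[unit])[response].mean().reset_index()

    samples, labels, excluded = [], [], []
    for loc, sub in agg.groupby("lesion_location"):
        if len(sub) < 2:
            warnings.warn(
                f"location {loc!r} has <2 observations; excluded", stacklevel=2
            )
            excluded.append(str(loc))
            continue
        samples.append(sub[response].to_numpy())
        labels.append(str(loc))
    if len(samples) < 2:
        raise ValueError("need at least 2 locations with >=2 observations")

    pooled = np.concatenate(samples)
    if float(np.ptp(pooled)) == 0.0:
        warnings.warn("zero variance across all groups; F undefined", stacklevel=2)
        f_val, p_val = np.nan, np.nan
    else:
        f_val, p_val = st.f_oneway(*samples)

    m = len(labels) * (len(labels) - 1) // 2
    pair_rows = []
    for (i, a), (j, b) in combinations(enumerate(labels), 2):
        t, p = st.ttest_ind(samples[i], samples[j], equal_var=True)
        pair_rows.append(
            {
                "location_a": a,
                "location_b": b,
                "t_stat": float(t),
                "pvalue_raw": float(p),
                "pvalue_bonferroni": float(min(1.0, m * p)),
            }
        )
    means = pd.DataFrame(
        {
            "lesion_location": labels,
            "mean": [s.mean() for s in samples],
            "sem": [st.sem(s) for s in samples],
            "n": [len(s) for s in samples],
        }
    )
    return AnovaResult(
        f_stat=float(f_val),
        pvalue=float(p_val),
        df_between=len(labels) - 1,
        df_within=sum(len(s) for s in samples) - len(labels),
        group_means=means,
        pairwise=pd.DataFrame(pair_rows),
        excluded_groups=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# report assembly

CELL_ORDER = ("CTRL_TP1", "P_TP1", "P_TP2", "P_TP3")

#: minimal schema of the analysis report (key -> required type)
REPORT_SCHEMA: Mapping[str, type] = {
    "resilience_summary": list,
    "baseline_summary": list,
    "resilience_models": dict,
    "contrast_table": list,
    "pc_summary": list,
    "hub_nodes": list,
    "anti_hub_nodes": list,
    "pc_correlations": list,
    "weibull_fits": list,
    "factor_models": dict,
    "location_anova": dict,
}


def validate_report(report: Mapping) -> None:
    """Check the report against the package's published schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report key {key!r} must be {typ.__name__}, "
                f"got {type(report[key]).__name__}"
            )


def _cell_contrast_spec(response: str) -> ModelSpec:
    cells = CELL_ORDER
    return ModelSpec(
        response=response,
        fixed_effects=("cell",),
        contrasts=tuple(
            ("cell", a, b) for a, b in combinations(cells, 2)
        ),
    )


def _records(df: pd.DataFrame) -> list[dict]:
    return df.replace({np.nan: None}).to_dict(orient="records")


def build_report(
    outcomes: pd.DataFrame,
    pc_table: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    k_hubs: int = 10,
    fit_weibull: bool = True,
) -> dict:
    """Assemble the full analysis report as a JSON-serializable dict.

    Inputs are the attack-outcome table (long format, one row per subject x
    timepoint x mask x metric), the nodal-PC table and the subject table.
    The report mirrors the result structure of the analysis: resilience and
    baseline summaries per design cell, mixed-model contrast table with
    report-wide BH-FDR, hub/anti-hub PC comparisons and correlations with
    resilience, exponentiated-Weibull fits of the PC distribution, patient/
    lesion factor models and the lesion-location ANOVA.
    """
    from .hub_analysis import (
        fit_exponentiated_weibull,
        pc_group_summaries,
        rank_nodes_by_control_pc,
        spearman_corr,
    )

    for name, df in (("outcomes", outcomes), ("pc_table", pc_table),
                     ("subjects", subjects)):
        if df is None or len(df) == 0:
            raise ValueError(f"missing upstream table: {name}")

    usable = outcomes.dropna(subset=["r_norm"])
    usable = attach_cells(usable)

    resilience_summary = (
        usable.groupby(["metric", "cell"])["r_norm"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    baseline = (
        usable.groupby(["metric", "cell", "subject_id", "timepoint"])["m_pre"]
        .first()
        .reset_index()
        .groupby(["metric", "cell"])["m_pre"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )

    # mixed models per metric; BH across the report's whole contrast table
    models: dict[str, dict] = {}
    contrast_frames = []
    for metric in sorted(usable["metric"].unique()):
        sub = usable[usable["metric"] == metric]
        res = fit_mixed_model(sub, _cell_contrast_spec("r_norm"))
        models[metric] = {
            "params": {k: float(v) for k, v in res.params.items()},
            "converged": res.converged,
            "n_obs": res.n_obs,
            "n_subjects": res.n_groups,
        }
        ctab = res.contrasts.copy()
        ctab.insert(0, "metric", metric)
        contrast_frames.append(ctab)
    contrast_table = pd.concat(contrast_frames, ignore_index=True)
    valid = contrast_table["pvalue"].notna()
    adjusted = np.full(len(contrast_table), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = bh_fdr(contrast_table.loc[valid, "pvalue"])
    contrast_table["pvalue_fdr"] = adjusted
    contrast_table["significant"] = contrast_table["pvalue_fdr"] < alpha

    # hub / anti-hub PC analysis
    top, bottom = rank_nodes_by_control_pc(pc_table, k=k_hubs)
    pc_summary = pc_group_summaries(pc_table, top, bottom)

    pat_pc = pc_table[pc_table["group"] == "patient"]
    pat_out = usable[usable["group"] == "patient"]
    mean_rnorm = (
        pat_out.groupby(["subject_id", "timepoint", "metric"])["r_norm"]
        .mean()
        .unstack("metric")
        .reset_index()
    )
    corr_rows = []
    for node_set, nodes in (("hub", top), ("anti_hub", bottom)):
        mean_pc = (
            pat_pc[pat_pc["node_id"].isin(nodes)]
            .groupby(["subject_id", "timepoint"])["pc"]
            .mean()
            .reset_index()
        )
        joined = mean_pc.merge(mean_rnorm, on=["subject_id", "timepoint"])
        for metric in ("global_efficiency", "modularity"):
            if metric not in joined.columns:
                continue
            sub = joined.dropna(subset=[metric])
            try:
                rho = spearman_corr(sub["pc"], sub[metric])
            except ValueError:
                rho = np.nan
            corr_rows.append(
                {
                    "node_set": node_set,
                    "metric": metric,
                    "rho": rho,
                    "n": len(sub),
                }
            )

    weibull_rows = []
    if fit_weibull:
        groups = [("control", pc_table[pc_table["group"] == "control"])]
        for tp, sub in pc_table[pc_table["group"] == "patient"].groupby(
            "timepoint"
        ):
            groups.append((f"patient_{tp}", sub))
        for label, sub in groups:
            vals = sub["pc"].to_numpy()
            vals = vals[vals > 0]
            try:
                fit = fit_exponentiated_weibull(vals)
                weibull_rows.append(
                    {
                        "group": label,
                        "shape_a": fit.shape_a,
                        "shape_c": fit.shape_c,
                        "scale": fit.scale,
                        "skewness": fit.skewness,
                        "log_likelihood": fit.log_likelihood,
                        "converged": fit.converged,
                    }
                )
            except ValueError as exc:
                weibull_rows.append({"group": label, "error": str(exc)})

    # patient / lesion factor models (Table-2 shape)
    factor_models: dict[str, dict] = {}
    pat_rows = usable[usable["group"] == "patient"].merge(
        subjects, on="subject_id", how="left", suffixes=("", "_subj")
    )
    factor_cols = ("timepoint", "age", "sex", "nihss", "lesion_size",
                   "lesion_type", "lesion_location")
    have_factors = all(c in pat_rows.columns for c in factor_cols)
    if have_factors:
        for metric in ("global_efficiency", "modularity"):
            sub = pat_rows[pat_rows["metric"] == metric].dropna(
                subset=["r_norm", *factor_cols]
            )
            if sub.empty:
                continue
            spec = ModelSpec(response="r_norm", fixed_effects=factor_cols)
            try:
                res = fit_mixed_model(sub, spec)
            except ValueError as exc:
                factor_models[metric] = {"error": str(exc)}
                continue
            ci = res.conf_int
            factor_models[metric] = {
                "coefficients": [
                    {
                        "term": term,
                        "estimate": float(res.params[term]),
                        "se": float(res.bse[term]),
                        "ci_low": float(ci.loc[term, 0]),
                        "ci_high": float(ci.loc[term, 1]),
                        "pvalue": float(res.pvalues[term]),
                    }
                    for term in res.params.index
                ],
                "n_obs": res.n_obs,
            }

    location_anova: dict[str, dict] = {}
    if "lesion_location" in subjects.columns:
        for metric in ("global_efficiency", "modularity"):
            sub = usable[usable["metric"] == metric]
            try:
                res = anova_by_location(sub, subjects)
            except ValueError as exc:
                location_anova[metric] = {"error": str(exc)}
                continue
            location_anova[metric] = {
                "f_stat": res.f_stat,
                "pvalue": res.pvalue,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "group_means": _records(res.group_means),
                "pairwise_bonferroni": _records(res.pairwise),
            }

    report = {
        "resilience_summary": _records(resilience_summary),
        "baseline_summary": _records(baseline),
        "resilience_models": models,
        "contrast_table": _records(contrast_table),
        "pc_summary": _records(pc_summary),
        "hub_nodes": list(top),
        "anti_hub_nodes": list(bottom),
        "pc_correlations": corr_rows,
        "weibull_fits": weibull_rows,
        "factor_models": factor_models,
        "location_anova": location_anova,
    }
    validate_report(report)
    return report
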