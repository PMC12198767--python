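"""Mixed models, FDR, subsample balance check, location ANOVA, report."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from connres.io import subjects_to_frame
from connres.stats_report import (
    ModelSpec,
    anova_by_location,
    attach_cells,
    bh_fdr,
    build_report,
    fit_mixed_model,
    subsample_balance_check,
    validate_report,
)


def balanced_table(seed=0, n_subjects=30, subject_sd=0.0):
    """Every subject sees the same within-subject design block."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, subject_sd)
        for level, x in zip("ABC", (0.0, 1.0, 2.0)):
            rows.append(
                {
                    "subject_id": f"S{s:02d}",
                    "treatment": level,
                    "x": x,
                    "y": intercept
                    + 0.5 * x
                    + (0.3 if level == "B" else 0.0)
                    + rng.normal(0, 0.2),
                }
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_balanced_design_matches_ols(self):
        table = balanced_table(seed=1)
        spec = ModelSpec(response="y", fixed_effects=("treatment",))
        res = fit_mixed_model(table, spec)
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ C(treatment)", table).fit()
        for name in res.params.index:
            assert res.params[name] == pytest.approx(
                ols.params[name], abs=1e-6
            )

    def test_zero_response_gives_zero_coefficients(self):
        table = balanced_table(seed=2)
        table["y"] = 0.0
        res = fit_mixed_model(
            table, ModelSpec(response="y", fixed_effects=("treatment",))
        )
        assert np.allclose(res.params.to_numpy(), 0.0, atol=1e-8)

    def test_singular_design_names_collinear_columns(self):
        table = balanced_table(seed=3)
        table["x_copy"] = table["x"]
        with pytest.raises(ValueError, match="x_copy"):
            fit_mixed_model(
                table, ModelSpec(response="y", fixed_effects=("x", "x_copy"))
            )

    def test_missing_column_and_response_guards(self):
        table = balanced_table(seed=4)
        with pytest.raises(ValueError, match="missing"):
            fit_mixed_model(
                table, ModelSpec(response="y", fixed_effects=("nope",))
            )
        table.loc[0, "y"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            fit_mixed_model(
                table, ModelSpec(response="y", fixed_effects=("treatment",))
            )

    def test_contrast_recovers_injected_cell_difference(self):
        table = balanced_table(seed=5, n_subjects=60, subject_sd=0.3)
        spec = ModelSpec(
            response="y",
            fixed_effects=("treatment",),
            contrasts=(("treatment", "B", "A"),),
        )
        res = fit_mixed_model(table, spec)
        row = res.contrasts.iloc[0]
        # the generating process moves B above A by 0.3 (cell shift) plus
        # 0.5 (the covariate step that tracks the level)
        assert row["estimate"] == pytest.approx(0.8, abs=0.15)
        assert row["pvalue"] < 0.01

    def test_group_effect_recovered_on_effect_cohort(
        self, small_battery
    ):
        """Injected hub de-concentration shows up as a positive patient
        coefficient for global-efficiency resilience."""
        out = small_battery.outcomes
        eg = out[(out["metric"] == "global_efficiency") & ~out["excluded"]]
        res = fit_mixed_model(
            eg, ModelSpec(response="r_norm", fixed_effects=("group",))
        )
        assert res.coef("patient") > 0


class TestBhFdr:
    def test_textbook_step_up(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_inputs_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(
        hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=20),
        hst.integers(0, 2**30 - 1),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_permutation_invariant_and_dominated_by_bonferroni(self, ps, seed):
        ps = np.asarray(ps)
        adj = bh_fdr(ps)
        assert np.all(adj <= 1.0) and np.all(adj >= ps - 1e-15)
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj_perm = bh_fdr(ps[perm])
        assert np.allclose(adj_perm[np.argsort(perm)], adj)
        bonferroni = np.minimum(1.0, len(ps) * ps)
        assert np.all(bonferroni >= adj - 1e-12)


class TestSubsampleBalance:
    def _tables(self, seed=0, n_patients=30):
        rng = np.random.default_rng(seed)
        def rows(prefix, group, n, shift):
            return pd.DataFrame(
                {
                    "subject_id": np.repeat(
                        [f"{prefix}{i:02d}" for i in range(n)], 5
                    ),
                    "group": group,
                    "r_norm": rng.normal(shift, 1.0, n * 5),
                }
            )
        return rows("P", "patient", n_patients, 0.3), rows("C", "control", 18, 0.0)

    def test_four_replicates_of_eighteen(self):
        pats, ctrls = self._tables()
        res = subsample_balance_check(pats, ctrls, seed=7)
        assert len(res) == 4
        assert (res["n_patients"] == 18).all()
        for ids in res["patient_ids"]:
            assert len(ids.split(",")) == 18

    def test_deterministic_under_seed(self):
        pats, ctrls = self._tables()
        a = subsample_balance_check(pats, ctrls, seed=3)
        b = subsample_balance_check(pats, ctrls, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_patients_rejected(self):
        pats, ctrls = self._tables(n_patients=10)
        with pytest.raises(ValueError, match="n_draw"):
            subsample_balance_check(pats, ctrls)

    def test_null_replicates_have_no_systematic_sign(self, null_runs):
        estimates = np.concatenate(
            [run["balance_estimates"] for run in null_runs]
        )
        frac_positive = float(np.mean(estimates > 0))
        assert 0.25 <= frac_positive <= 0.75


class TestAnovaByLocation:
    def _outcomes(self, groups: dict, seed=0):
        rng = np.random.default_rng(seed)
        out_rows, subj_rows = [], []
        i = 0
        for loc, (n, mean) in groups.items():
            for _ in range(n):
                sid = f"P{i:03d}"
                i += 1
                subj_rows.append(
                    {"subject_id": sid, "lesion_location": loc}
                )
                for tp in ("TP1", "TP2"):
                    for mask in ("M1", "M2", "M3"):
                        out_rows.append(
                            {
                                "subject_id": sid,
                                "group": "patient",
                                "timepoint": tp,
                                "mask_id": mask,
                                "r_norm": rng.normal(mean, 0.5),
                            }
                        )
        return pd.DataFrame(out_rows), pd.DataFrame(subj_rows)

    def test_two_groups_f_equals_t_squared(self):
        out, subj = self._outcomes({"cortical": (8, 0.5), "brainstem": (7, 0.0)})
        res = anova_by_location(out, subj)
        agg = (
            out.merge(subj, on="subject_id")
            .groupby(["subject_id", "mask_id", "lesion_location"])["r_norm"]
            .mean()
            .reset_index()
        )
        a = agg[agg["lesion_location"] == "cortical"]["r_norm"]
        b = agg[agg["lesion_location"] == "brainstem"]["r_norm"]
        t, _ = st.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)

    def test_three_group_toy_matches_textbook_formula(self):
        out, subj = self._outcomes(
            {"cortical": (6, 0.8), "subcortical": (6, 0.2), "cerebellum": (5, 0.0)}
        )
        res = anova_by_location(out, subj)
        agg = (
            out.merge(subj, on="subject_id")
            .groupby(["subject_id", "mask_id", "lesion_location"])["r_norm"]
            .mean()
            .reset_index()
        )
        samples = [
            g["r_norm"].to_numpy()
            for _, g in agg.groupby("lesion_location")
        ]
        grand = np.concatenate(samples).mean()
        ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
        k, n = len(samples), sum(len(s) for s in samples)
        f_hand = (ss_b / (k - 1)) / (ss_w / (n - k))
        assert res.f_stat == pytest.approx(f_hand, rel=1e-10)
        assert res.df_between == 2 and res.df_within == n - 3
        m = 3  # pairwise comparisons
        for _, row in res.pairwise.iterrows():
            assert row["pvalue_bonferroni"] == pytest.approx(
                min(1.0, m * row["pvalue_raw"])
            )

    def test_constant_outcomes_flagged(self):
        out, subj = self._outcomes({"cortical": (4, 0.0), "brainstem": (4, 0.0)})
        out["r_norm"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            res = anova_by_location(out, subj)
        assert np.isnan(res.f_stat)

    def test_small_group_excluded_with_warning(self):
        out, subj = self._outcomes({"cortical": (6, 0.3), "brainstem": (5, 0.0)})
        # a location contributed by a single patient with a single row
        out = pd.concat(
            [
                out,
                pd.DataFrame(
                    [
                        {
                            "subject_id": "P999",
                            "group": "patient",
                            "timepoint": "TP1",
                            "mask_id": "M1",
                            "r_norm": 0.1,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
        subj = pd.concat(
            [
                subj,
                pd.DataFrame(
                    [{"subject_id": "P999", "lesion_location": "white matter"}]
                ),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="white matter"):
            res = anova_by_location(out, subj)
        assert res.excluded_groups == ("white matter",)


class TestReport:
    def test_missing_upstream_table_named(self, small_battery, small_pc_table):
        with pytest.raises(ValueError, match="subjects"):
            build_report(
                small_battery.outcomes, small_pc_table, pd.DataFrame()
            )
        with pytest.raises(ValueError, match="outcomes"):
            build_report(
                pd.DataFrame(), small_pc_table, pd.DataFrame({"a": [1]})
            )

    def test_full_synthetic_run_validates_against_schema(
        self, small_cohort, small_battery, small_pc_table
    ):
        subjects = subjects_to_frame(small_cohort.subjects)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = build_report(
                small_battery.outcomes, small_pc_table, subjects
            )
        validate_report(report)  # raises on schema violation
        assert len(report["hub_nodes"]) == 10
        cells = {r["cell"] for r in report["resilience_summary"]}
        assert cells == {"CTRL_TP1", "P_TP1", "P_TP2", "P_TP3"}
        import json

        json.dumps(report)  # fully serializable

    def test_validate_report_rejects_missing_key(self):
        with pytest.raises(ValueError, match="resilience_summary"):
            validate_report({})

    def test_attach_cells_labels(self):
        df = pd.DataFrame(
            {
                "group": ["control", "patient"],
                "timepoint": ["TP1", "TP3"],
            }
        )
        assert list(attach_cells(df)["cell"]) == ["CTRL_TP1", "P_TP3"]
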