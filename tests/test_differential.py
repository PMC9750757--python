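"""Differential statistics: BH adjustment, normality-gated two-group tests,
heatmap z-scores, volcano tables, omnibus tests and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_bh, exact_mwu_p, grouping_from_meta
from traumapanel import (
    ExpressionMatrix,
    PanelError,
    adjust_bh,
    cohort_summary,
    compare_multi_groups,
    compare_two_groups,
    volcano_table,
    zscore_matrix,
)
from traumapanel.differential import FOLD_THRESHOLD_LOG2, dunn_posthoc


class TestAdjustBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([0.04, 0.01, 0.03, 0.005], [0.04, 0.02, 0.04, 0.02]),
    ])
    def test_hand_computed_step_up(self, p, expected):
        assert adjust_bh(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_matches_brute_force_and_dominates_input(self, p):
        adj = adjust_bh(p)
        assert adj == pytest.approx(brute_force_bh(p))
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestCompareTwoGroups:
    def test_forced_mwu_exact_small(self):
        res = compare_two_groups([1, 2], [3, 4], force="mann_whitney")
        assert res.p_raw == pytest.approx(1 / 3)
        assert res.test_used == "mann_whitney"

    def test_identical_multisets_null(self):
        res = compare_two_groups([1, 5, 9, 2], [9, 1, 2, 5], force="mann_whitney")
        assert res.log2fc == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_log2fc_is_mean_difference(self):
        res = compare_two_groups([4, 4, 4], [5, 5, 5], force="t")
        assert res.log2fc == pytest.approx(1.0)  # one log2 unit = 2-fold

    def test_small_groups_untestable_without_force(self):
        res = compare_two_groups([1, 2], [3, 4])
        assert not res.testable and res.p_raw is None

    def test_normality_gate_selects_t_for_gaussian(self):
        rng = np.random.default_rng(0)
        res = compare_two_groups(rng.normal(0, 1, 40), rng.normal(1, 1, 40))
        assert res.test_used == "t"

    def test_normality_gate_selects_mwu_for_skewed(self):
        rng = np.random.default_rng(0)
        res = compare_two_groups(rng.lognormal(0, 2, 40), rng.lognormal(1, 2, 40))
        assert res.test_used == "mann_whitney"

    @pytest.mark.parametrize("seed", range(8))
    def test_mwu_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 7, size=2)
        a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)
        res = compare_two_groups(a, b, force="mann_whitney")
        assert res.p_raw == pytest.approx(exact_mwu_p(a, b))


def _matrix_from_frame(df, meta):
    return ExpressionMatrix(values=df, scale="log2", sample_meta=meta)


@pytest.fixture()
def grouped_matrix():
    """3 analytes x 12 samples over two groups and two timepoints."""
    rng = np.random.default_rng(11)
    samples = [f"S{i}" for i in range(12)]
    meta = pd.DataFrame({
        "group": ["R"] * 3 + ["NR"] * 3 + ["R"] * 3 + ["NR"] * 3,
        "timepoint": ["0h"] * 6 + ["72h"] * 6,
        "patient_id": [f"P{i}" for i in range(12)],
    }, index=pd.Index(samples, name="sample_id"))
    values = pd.DataFrame(rng.normal(10, 1, (3, 12)),
                          index=["A0", "A1", "A2"], columns=samples)
    return _matrix_from_frame(values, meta), meta


class TestZScoreMatrix:
    def test_three_cell_row_standardization(self):
        # cell means [1,2,3] with sample SD 1 -> z = [-1, 0, 1]
        samples = ["a", "b", "c"]
        meta = pd.DataFrame({
            "group": ["G1", "G2", "G3"], "timepoint": ["0h"] * 3,
        }, index=pd.Index(samples, name="sample_id"))
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"], columns=samples)
        heat = zscore_matrix(_matrix_from_frame(values, meta),
                             grouping_from_meta(meta), compare=None)
        assert heat.z.loc["A"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_row_mean_zero_sd_one(self, grouped_matrix):
        m, meta = grouped_matrix
        heat = zscore_matrix(m, grouping_from_meta(meta), compare=None)
        assert heat.z.mean(axis=1).abs().max() < 1e-9
        assert (heat.z.std(axis=1, ddof=1) - 1).abs().max() < 1e-9

    def test_constant_row_zero_with_flag(self):
        samples = ["a", "b", "c"]
        meta = pd.DataFrame({
            "group": ["G1", "G2", "G3"], "timepoint": ["0h"] * 3,
        }, index=pd.Index(samples, name="sample_id"))
        values = pd.DataFrame([[5.0, 5.0, 5.0]], index=["A"], columns=samples)
        heat = zscore_matrix(_matrix_from_frame(values, meta),
                             grouping_from_meta(meta), compare=None)
        assert heat.degenerate.loc["A"]
        assert (heat.z.loc["A"] == 0).all()

    def test_unsampled_cells_absent_not_zero(self, default_cohort):
        _, matrix, truth = default_cohort
        from traumapanel import preprocess_panel

        manifest = truth.table[["symbol", "family", "role"]]
        log2m, _ = preprocess_panel(matrix, manifest, roles=("mediator",))
        heat = zscore_matrix(
            log2m, grouping_from_meta(matrix.sample_meta), compare=None
        )
        assert "ENS_0h" in heat.z.columns
        assert "ENS_24h" not in heat.z.columns

    def test_requires_log2(self, grouped_matrix):
        m, meta = grouped_matrix
        raw = ExpressionMatrix(values=2 ** m.values, scale="raw",
                               sample_meta=m.sample_meta)
        with pytest.raises(PanelError):
            zscore_matrix(raw, grouping_from_meta(meta))


class TestVolcano:
    def test_significance_rule(self, grouped_matrix):
        m, meta = grouped_matrix
        v = volcano_table(m, grouping_from_meta(meta), "72h")
        recomputed = (v["log2fc"].abs() >= FOLD_THRESHOLD_LOG2) & (v["p_adj"] < 0.05)
        assert (v["significant"] == recomputed).all()
        assert (v["p_adj"] >= v["p_raw"] - 1e-12).all()
        assert (v["test_used"] == "mann_whitney").all()

    def test_fold_threshold_boundary(self):
        assert 0.60 >= FOLD_THRESHOLD_LOG2
        assert 0.58 < FOLD_THRESHOLD_LOG2

    def test_direction_is_nr_minus_r(self):
        samples = [f"S{i}" for i in range(8)]
        meta = pd.DataFrame({
            "group": ["R"] * 4 + ["NR"] * 4, "timepoint": ["72h"] * 8,
        }, index=pd.Index(samples, name="sample_id"))
        values = pd.DataFrame([[1.0] * 4 + [3.0] * 4], index=["A"], columns=samples)
        v = volcano_table(_matrix_from_frame(values, meta),
                          grouping_from_meta(meta), "72h")
        assert v.loc["A", "log2fc"] == pytest.approx(2.0)

    def test_absent_timepoint_rejected(self, grouped_matrix):
        m, meta = grouped_matrix
        with pytest.raises(PanelError):
            volcano_table(m, grouping_from_meta(meta), "24h")


class TestMultiGroup:
    def test_identical_groups_null(self):
        groups = {g: [1.0, 1.0, 1.0] for g in "abc"}
        omnibus, pairwise = compare_multi_groups(groups)
        assert omnibus == 1.0
        assert all(p == 1.0 for p in pairwise.values())

    def test_separated_group_detected(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(3, 1, 20),
        }
        omnibus, pairwise = compare_multi_groups(groups)
        assert omnibus < 0.01
        assert len(pairwise) == 3  # C(3,2)
        assert pairwise[("a", "c")] < 0.01
        assert pairwise[("a", "b")] > 0.05

    def test_skewed_data_uses_kruskal_dunn(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.lognormal(0, 2, 25),
            "b": rng.lognormal(0, 2, 25),
            "c": rng.lognormal(2, 2, 25),
        }
        omnibus, pairwise = compare_multi_groups(groups)
        assert omnibus < 0.01
        assert pairwise[("a", "c")] < 0.05

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_multi_groups({"a": [1, 2, 3], "b": [4, 5, 6]})

    def test_dunn_symmetric_null_pair(self):
        rng = np.random.default_rng(9)
        shared = rng.normal(0, 1, 30)
        groups = {"a": shared, "b": shared.copy(), "c": shared + 5}
        p = dunn_posthoc(groups)
        assert p[("a", "b")] > 0.9
        assert p[("a", "c")] < 0.01


class TestCohortSummary:
    @pytest.fixture()
    def patients(self, default_cohort):
        plist, matrix, _ = default_cohort
        from traumapanel import patients_to_frame

        df = patients_to_frame(plist)
        groups = pd.Series(
            {p.patient_id: p.patient_id.rsplit("-", 1)[0] for p in plist}
        )
        return df, groups

    def test_sex_chi_square_matches_published_convention(self):
        # R 25M/9F vs NR 59M/19F gives chi-square p ~ 0.8124 without
        # continuity correction
        rows = []
        for g, m, f in (("R", 25, 9), ("NR", 59, 19)):
            for i in range(m):
                rows.append({"patient_id": f"{g}m{i}", "sex": "M", "grp": g})
            for i in range(f):
                rows.append({"patient_id": f"{g}f{i}", "sex": "F", "grp": g})
        df = pd.DataFrame(rows).set_index("patient_id")
        df["age"] = 40.0
        summary = cohort_summary(df, df["grp"])
        assert summary.loc["sex", "p_value"] == pytest.approx(0.8124, abs=5e-4)

    def test_full_cohort_summary_structure(self, patients):
        df, groups = patients
        trauma = df[~df["is_low_iss_control"]]
        summary = cohort_summary(trauma, groups[trauma.index])
        assert {"age", "iss", "sex", "arm"} <= set(summary.index)
        # NR vs R ISS difference is the calibrated large contrast
        assert summary.loc["iss", "p_value"] < 0.001
        assert summary.loc["age", "p_value"] > 0.05

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({
            "age": [30, 40, 50, 30, 40, 50],
            "sex": ["M", "F", "M", "M", "F", "M"],
        }, index=[f"p{i}" for i in range(6)])
        groups = pd.Series(["R"] * 3 + ["NR"] * 3, index=df.index)
        summary = cohort_summary(df, groups)
        assert summary.loc["age", "p_value"] == pytest.approx(1.0)

    def test_single_sex_degenerate_flagged_not_crash(self):
        df = pd.DataFrame({
            "age": [30, 40, 50, 31, 41, 51],
            "sex": ["M"] * 6,
        }, index=[f"p{i}" for i in range(6)])
        groups = pd.Series(["R"] * 3 + ["NR"] * 3, index=df.index)
        summary = cohort_summary(df, groups)
        assert summary.loc["sex", "test_used"] == "chi2_degenerate"
        assert np.isnan(summary.loc["sex", "p_value"])
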