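import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expression
from sliminer.cancer_specificity import (
    CalibrationSet,
    anchor_reduction,
    calibration_normalize_protein,
    calibration_normalize_rna,
    group_compare,
)
from sliminer.core_data import Scale


class TestAnchorReduction:
    def test_sixty_four_percent(self):
        healthy = make_expression([[10.0, 10.0]], genes=["A"], scale=Scale.linear_tpm)
        tumor = make_expression([[3.6, 3.6]], genes=["A"], scale=Scale.linear_tpm)
        rec = anchor_reduction("A", tumor, healthy)
        assert rec.reduction_pct == pytest.approx(64.0)

    def test_increase_clips_to_zero(self):
        healthy = make_expression([[10.0]], genes=["A"], scale=Scale.linear_tpm)
        tumor = make_expression([[12.0]], genes=["A"], scale=Scale.linear_tpm)
        assert anchor_reduction("A", tumor, healthy).reduction_pct == 0.0

    def test_equal_means_zero(self):
        m = make_expression([[5.0, 7.0]], genes=["A"], scale=Scale.linear_tpm)
        assert anchor_reduction("A", m, m).reduction_pct == 0.0

    def test_log_inputs_are_delogged(self):
        healthy = make_expression([[np.log2(10 + 1)]], genes=["A"])
        tumor = make_expression([[np.log2(3.6 + 1)]], genes=["A"])
        rec = anchor_reduction("A", tumor, healthy)
        assert rec.reduction_pct == pytest.approx(64.0, abs=1e-9)

    def test_zero_healthy_mean_undefined(self):
        healthy = make_expression([[0.0]], genes=["A"], scale=Scale.linear_tpm)
        tumor = make_expression([[1.0]], genes=["A"], scale=Scale.linear_tpm)
        with pytest.raises(ValueError, match="undefined"):
            anchor_reduction("A", tumor, healthy)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_reduction_always_in_range(self, mt, mh):
        tumor = make_expression([[mt]], genes=["A"], scale=Scale.linear_tpm)
        healthy = make_expression([[mh]], genes=["A"], scale=Scale.linear_tpm)
        rec = anchor_reduction("A", tumor, healthy)
        assert 0.0 <= rec.reduction_pct <= 100.0


class TestCalibrationRna:
    def cal(self):
        return CalibrationSet(("C1", "C2"))

    def test_constant_calibration_genes_are_identity(self):
        m = make_expression(
            [[3.0, 3.0, 3.0], [7.0, 7.0, 7.0], [1.0, 5.0, 9.0]],
            genes=["C1", "C2", "Q"], scale=Scale.linear_tpm,
        )
        out, excluded = calibration_normalize_rna([m], self.cal(), ["Q"])
        np.testing.assert_allclose(out["dataset_0"].loc["Q"], [1.0, 5.0, 9.0])
        assert excluded == []

    def test_per_sample_global_rescaling_invariance(self):
        """Against a frozen calibration reference, rescaling all genes of a
        sample by a constant leaves that sample's normalized query unchanged:
        the per-sample factor absorbs the constant exactly."""
        base = np.array([[2.0, 4.0], [6.0, 2.0], [10.0, 10.0]])
        m1 = make_expression(base, genes=["C1", "C2", "Q"], scale=Scale.linear_tpm)
        ref = {"C1": float(base[0].mean()), "C2": float(base[1].mean())}
        scaled = base * np.array([3.0, 0.5])  # rescale each sample globally
        m2 = make_expression(scaled, genes=["C1", "C2", "Q"], scale=Scale.linear_tpm)
        out1, _ = calibration_normalize_rna([m1], self.cal(), ["Q"], reference_means=ref)
        out2, _ = calibration_normalize_rna([m2], self.cal(), ["Q"], reference_means=ref)
        np.testing.assert_allclose(
            out1["dataset_0"].to_numpy(), out2["dataset_0"].to_numpy(), atol=1e-12
        )

    def test_rescaling_one_sample_in_large_cohort_is_near_invariant(self):
        """With grand means recomputed from the data, the invariance is
        asymptotic: one rescaled sample among many barely shifts the means."""
        rng = np.random.default_rng(0)
        n = 400
        base = rng.uniform(1, 20, size=(3, n))
        m1 = make_expression(base, genes=["C1", "C2", "Q"], scale=Scale.linear_tpm)
        scaled = base.copy()
        scaled[:, 0] *= 2.0
        m2 = make_expression(scaled, genes=["C1", "C2", "Q"], scale=Scale.linear_tpm)
        out1, _ = calibration_normalize_rna([m1], self.cal(), ["Q"])
        out2, _ = calibration_normalize_rna([m2], self.cal(), ["Q"])
        v1 = out1["dataset_0"].iloc[0, 0]
        v2 = out2["dataset_0"].iloc[0, 0]
        assert v2 == pytest.approx(v1, rel=0.02)

    def test_hand_arithmetic_oracle(self):
        # calibration TPMs [[2,4],[6,2]], query [10,10]:
        # scaled C1 = (2/3, 4/3), C2 = (6/4, 2/4)
        # f = ((2/3 + 6/4)/2, (4/3 + 2/4)/2) = (13/12, 11/12)
        # normalized query = (10/(13/12), 10/(11/12)) = (120/13, 120/11)
        m = make_expression(
            [[2.0, 4.0], [6.0, 2.0], [10.0, 10.0]],
            genes=["C1", "C2", "Q"], scale=Scale.linear_tpm,
        )
        out, _ = calibration_normalize_rna([m], self.cal(), ["Q"])
        np.testing.assert_allclose(out["dataset_0"].loc["Q"], [120 / 13, 120 / 11])

    def test_query_rescaling_equivariance(self):
        m = make_expression(
            [[2.0, 4.0], [6.0, 2.0], [10.0, 10.0]],
            genes=["C1", "C2", "Q"], scale=Scale.linear_tpm,
        )
        m3 = make_expression(
            [[2.0, 4.0], [6.0, 2.0], [30.0, 30.0]],
            genes=["C1", "C2", "Q"], scale=Scale.linear_tpm,
        )
        out1, _ = calibration_normalize_rna([m], self.cal(), ["Q"])
        out3, _ = calibration_normalize_rna([m3], self.cal(), ["Q"])
        np.testing.assert_allclose(
            3.0 * out1["dataset_0"].to_numpy(), out3["dataset_0"].to_numpy()
        )

    def test_union_grand_mean_couples_datasets(self):
        a = make_expression([[1.0], [1.0], [5.0]], genes=["C1", "C2", "Q"],
                            samples=["sa"], scale=Scale.linear_tpm)
        b = make_expression([[3.0], [3.0], [5.0]], genes=["C1", "C2", "Q"],
                            samples=["sb"], scale=Scale.linear_tpm)
        out, _ = calibration_normalize_rna([a, b], self.cal(), ["Q"])
        # grand mean = 2 -> f_a = 0.5, f_b = 1.5
        assert out["dataset_0"].loc["Q", "sa"] == pytest.approx(10.0)
        assert out["dataset_1"].loc["Q", "sb"] == pytest.approx(5 / 1.5)

    def test_zero_grand_mean_calibration_gene_errors(self):
        m = make_expression([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]],
                            genes=["C1", "C2", "Q"], scale=Scale.linear_tpm)
        with pytest.raises(ValueError, match="zero grand-mean"):
            calibration_normalize_rna([m], self.cal(), ["Q"])


class TestCalibrationProtein:
    def frame(self, values, proteins, samples):
        return pd.DataFrame(values, index=proteins, columns=samples)

    def test_unit_calibration_ratios_identity(self):
        # log2 ratios of 0 -> ratios of 1 everywhere
        df = self.frame(
            [[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]], ["C1", "C2", "Q"], ["s1", "s2"]
        )
        out, excluded = calibration_normalize_protein(df, ["C1", "C2"], "Q")
        np.testing.assert_allclose(out.to_numpy(), [2.0, 4.0])
        assert excluded == []

    def test_doubling_calibration_halves_query(self):
        base = self.frame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]], ["C1", "C2", "Q"], ["s1", "s2"])
        shifted = base.copy()
        shifted.loc[["C1", "C2"], "s2"] += 1.0  # doubles both calibration ratios in s2
        out_b, _ = calibration_normalize_protein(base, ["C1", "C2"], "Q")
        out_s, _ = calibration_normalize_protein(shifted, ["C1", "C2"], "Q")
        # averages move too; the s2/s1 ratio of normalized queries must halve
        assert (out_s["s2"] / out_s["s1"]) == pytest.approx(
            0.5 * (out_b["s2"] / out_b["s1"])
        )

    def test_geometric_mean_divisor(self):
        # one sample; calibration normalized ratios 2 and 8 -> divisor 4
        df = self.frame(
            [[1.0, 3.0], [1.0, 5.0], [2.0, 2.0]], ["C1", "C2", "Q"], ["s1", "s2"]
        )
        ratios = np.exp2(df)
        cal_norm = ratios.loc[["C1", "C2"]].div(
            ratios.loc[["C1", "C2"]].mean(axis=1), axis=0
        )
        expected_divisor = np.sqrt(cal_norm.loc["C1"] * cal_norm.loc["C2"])
        out, _ = calibration_normalize_protein(df, ["C1", "C2"], "Q")
        np.testing.assert_allclose(
            out.to_numpy(), (ratios.loc["Q"] / expected_divisor).to_numpy()
        )

    def test_missing_calibration_sample_excluded(self):
        df = self.frame(
            [[0.0, np.nan], [0.0, 0.0], [1.0, 1.0]], ["C1", "C2", "Q"], ["s1", "s2"]
        )
        out, excluded = calibration_normalize_protein(df, ["C1", "C2"], "Q")
        assert excluded == ["s2"]
        assert list(out.index) == ["s1"]


class TestGroupCompare:
    def test_identical_groups_no_change_no_significance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 1, size=50)
        res = group_compare({"a": v, "b": v.copy()}, test="two_group_rank")
        assert res[0].percent_change_of_mean == pytest.approx(0.0)
        assert res[0].p >= 0.05

    def test_sixty_four_percent_decrease(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(5, 15, size=30)
        res = group_compare({"a": a, "b": 0.36 * a}, test="two_group_rank")
        assert res[0].percent_change_of_mean == pytest.approx(-64.0)
        assert res[0].p < 0.001

    def test_omnibus_not_significant_suppresses_posthoc(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(0, 1, size=10) for k in "abc"}
        res = group_compare(groups, test="multi_group_rank_with_posthoc")
        from scipy import stats

        _, p_omni = stats.kruskal(*groups.values())
        if p_omni >= 0.05:
            assert all(c.p is None for c in res)

    def test_multi_group_detects_shifted_group(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0, 1, size=40),
            "b": rng.normal(0, 1, size=40),
            "c": rng.normal(5, 1, size=40),
        }
        res = group_compare(groups, test="multi_group_rank_with_posthoc")
        by_pair = {(c.group_a, c.group_b): c.p for c in res}
        assert by_pair[("a", "c")] < 0.001
        assert by_pair[("b", "c")] < 0.001
        assert by_pair[("a", "b")] > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 values"):
            group_compare({"a": [1.0], "b": [1.0, 2.0]}, test="two_group_rank")
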