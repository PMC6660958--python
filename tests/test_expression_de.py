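"""Paired and unpaired differential-expression statistics against exact oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slinet.expression_de import (
    PairedExpressionData,
    bh_adjust,
    call_regulation,
    differential_expression,
    filter_nonzero,
    fold_change,
    normality_summary,
    paired_wilcoxon,
    pan_cancer_profile,
    unpaired_compare,
)
from slinet.synthetic_data import simulate_paired_expression

from oracles import bh_oracle, mannwhitney_p_oracle, signed_rank_p_oracle, zero_filter_oracle


def make_data(tumor, normal, genes=None):
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    genes = genes or [f"G{i}" for i in range(tumor.shape[0])]
    patients = [f"P{i}" for i in range(tumor.shape[1])]
    return PairedExpressionData(
        tumor=pd.DataFrame(tumor, index=genes, columns=patients),
        normal=pd.DataFrame(normal, index=genes, columns=patients),
    )


class TestFilterNonzero:
    def test_single_zero_in_normal_removes_gene(self):
        data = make_data([[1, 2, 3], [4, 5, 6]], [[1, 0, 3], [4, 5, 6]])
        kept, removed = filter_nonzero(data)
        assert removed == ["G0"]
        assert kept.genes == ["G1"]

    def test_all_positive_matrix_removes_nothing(self):
        data = make_data([[1, 2], [3, 4]], [[5, 6], [7, 8]])
        kept, removed = filter_nonzero(data)
        assert removed == [] and kept.genes == ["G0", "G1"]

    def test_random_zero_pattern_matches_brute_force(self):
        rng = np.random.default_rng(11)
        tumor = rng.uniform(0, 5, size=(30, 8))
        normal = rng.uniform(0, 5, size=(30, 8))
        tumor[rng.random(tumor.shape) < 0.1] = 0
        normal[rng.random(normal.shape) < 0.1] = 0
        data = make_data(tumor, normal)
        kept, _ = filter_nonzero(data)
        expected = [f"G{i}" for i in zero_filter_oracle(tumor, normal)]
        assert kept.genes == expected


class TestPairedWilcoxon:
    def test_five_identical_positive_shifts(self):
        out = paired_wilcoxon([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert out.p_value == pytest.approx(0.0625)
        assert out.n_effective == 5 and not out.degenerate

    def test_identical_rows_degenerate(self):
        out = paired_wilcoxon([1, 2, 3], [1, 2, 3])
        assert out.p_value == 1.0 and out.degenerate

    def test_zero_differences_dropped_before_ranking(self):
        a = paired_wilcoxon([2, 3, 4, 5, 1], [1, 2, 3, 4, 1])
        b = paired_wilcoxon([2, 3, 4, 5], [1, 2, 3, 4])
        assert a.n_effective == b.n_effective == 4
        assert a.p_value == pytest.approx(b.p_value)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.integers(-20, 20).filter(lambda v: v != 0), min_size=2, max_size=10
        )
    )
    def test_matches_exhaustive_sign_flip_enumeration(self, diffs):
        normal = np.arange(100.0, 100.0 + len(diffs))
        tumor = normal + np.array(diffs, dtype=float)
        out = paired_wilcoxon(tumor, normal)
        assert out.p_value == pytest.approx(signed_rank_p_oracle(diffs), abs=1e-9)

    def test_large_n_uses_continuity_corrected_normal(self):
        rng = np.random.default_rng(0)
        normal = rng.uniform(10, 20, 60)
        tumor = normal * 2 ** rng.normal(0.4, 0.3, 60)
        out = paired_wilcoxon(tumor, normal)
        assert 0 < out.p_value < 0.05  # strong planted shift at n=60

    def test_too_short_rows_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0], [2.0])


class TestBHAdjust:
    def test_equally_spaced_quartet(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_step_up_oracle_on_many_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestFoldChange:
    def test_uniform_quarter_expression_gives_minus_two(self):
        assert fold_change([50, 50, 50], [200, 200, 200]) == pytest.approx(-2.0)

    def test_equal_rows_give_zero(self):
        assert fold_change([7, 8], [7, 8]) == 0.0

    def test_mean_of_per_patient_ratios_not_ratio_of_means(self):
        tumor, normal = [2.0, 16.0], [1.0, 1.0]
        # per-patient log2 ratios are 1 and 4 -> mean 2.5
        assert fold_change(tumor, normal) == pytest.approx(2.5)
        assert fold_change(tumor, normal) != pytest.approx(np.log2(9.0))

    def test_zero_value_rejected(self):
        with pytest.raises(ValueError):
            fold_change([0, 1], [1, 1])


class TestCallRegulation:
    @pytest.mark.parametrize(
        "lfc,p_adj,status",
        [
            (-1.5, 0.01, "down"),
            (-0.5, 0.001, "ns"),
            (-1.0, 0.04, "down"),   # boundary fold change is inclusive
            (1.5, 0.01, "up"),
            (-1.5, 0.05, "ns"),     # alpha boundary is strict
        ],
    )
    def test_call_rules(self, lfc, p_adj, status):
        df = pd.DataFrame({"gene": ["g"], "mean_log2_ratio": [lfc], "p_adj": [p_adj]})
        assert call_regulation(df)["status"].iloc[0] == status


class TestNormalitySummary:
    def test_gaussian_data_passes_at_expected_rate(self):
        rng = np.random.default_rng(8)
        fracs = []
        for seed_offset in range(3):
            rng = np.random.default_rng(100 + seed_offset)
            values = rng.normal(100, 10, size=(300, 114))
            data = make_data(np.abs(values), np.abs(rng.normal(100, 10, size=(300, 114))))
            s = normality_summary(data)
            fracs.extend([s.frac_normal_tumor, s.frac_normal_normal])
        assert np.mean(fracs) == pytest.approx(0.95, abs=0.03)

    def test_exponential_data_fails_normality(self):
        rng = np.random.default_rng(9)
        data = make_data(
            rng.exponential(50, size=(100, 114)), rng.exponential(50, size=(100, 114))
        )
        s = normality_summary(data)
        assert s.frac_normal_tumor < 0.5 and s.frac_normal_normal < 0.5

    def test_constant_gene_is_indeterminate(self):
        data = make_data(
            [[5.0] * 10, list(range(1, 11))], [list(range(1, 11)), list(range(1, 11))]
        )
        s = normality_summary(data)
        assert s.n_indeterminate_tumor == 1


class TestUnpairedCompare:
    def test_separated_triples_exact_p(self):
        tumor = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        normal = pd.DataFrame([[4.0, 5.0, 6.0]], index=["g"])
        res = unpaired_compare(tumor, normal)
        assert res.loc["g", "p_value"] == pytest.approx(0.1)
        assert res.loc["g", "direction"] == "down"

    def test_identical_groups_p_one(self):
        tumor = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"])
        normal = pd.DataFrame([[2.0, 2.0]], index=["g"])
        res = unpaired_compare(tumor, normal)
        assert res.loc["g", "p_value"] == 1.0

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 100), min_size=4, max_size=12, unique=True),
        st.integers(2, 10),
    )
    def test_matches_exhaustive_permutation_oracle(self, pooled, cut):
        cut = min(max(cut, 2), len(pooled) - 2)
        x, y = pooled[:cut], pooled[cut:]
        tumor = pd.DataFrame([list(map(float, x))], index=["g"])
        normal = pd.DataFrame([list(map(float, y))], index=["g"])
        p = unpaired_compare(tumor, normal).loc["g", "p_value"]
        if len(x) <= 8 and len(y) <= 8:  # exact path
            assert p == pytest.approx(mannwhitney_p_oracle(x, y), abs=1e-9)
        else:
            assert 0 < p <= 1

    def test_tied_data_close_to_permutation_oracle(self):
        x, y = [1.0, 2.0, 2.0, 5.0, 7.0], [2.0, 4.0, 6.0, 6.0, 8.0]
        tumor = pd.DataFrame([x], index=["g"])
        normal = pd.DataFrame([y], index=["g"])
        p = unpaired_compare(tumor, normal).loc["g", "p_value"]
        assert p == pytest.approx(mannwhitney_p_oracle(x, y), abs=0.1)


class TestPanCancerProfile:
    @staticmethod
    def profile(n_down, n_total=15):
        genes = [f"g{i}" for i in range(n_total)]
        res = pd.DataFrame(
            {
                "p_value": [0.01] * n_down + [0.5] * (n_total - n_down),
                "direction": ["down"] * n_total,
            },
            index=genes,
        )
        return genes, {"CANCER": res}

    @pytest.mark.parametrize("n_down,included", [(8, True), (7, False), (0, False)])
    def test_strictly_more_than_seven_rule(self, n_down, included):
        genes, per_cancer = self.profile(n_down)
        matrix, inc = pan_cancer_profile(per_cancer, genes)
        assert bool(inc["CANCER"]) is included
        assert (matrix["CANCER"] == "down").sum() == n_down


class TestPipelineProperties:
    def test_scale_invariance(self):
        data, _ = simulate_paired_expression(
            n_genes=30, n_patients=20, n_down=5, log2fc=-1.5, sigma=0.3,
            zero_rate=0.0, seed=21,
        )
        base = differential_expression(data, run_normality=False)
        scaled = PairedExpressionData(tumor=data.tumor * 37.5, normal=data.normal * 37.5)
        res = differential_expression(scaled, run_normality=False)
        assert np.allclose(base["p_raw"], res["p_raw"])
        assert np.allclose(base["mean_log2_ratio"], res["mean_log2_ratio"])

    def test_permuting_pairing_destroys_planted_signal(self):
        data, truth = simulate_paired_expression(
            n_genes=60, n_patients=40, n_down=10, log2fc=-0.6, sigma=0.25,
            zero_rate=0.0, seed=22,
        )
        paired = differential_expression(data, fc_cut_log2=0.0, run_normality=False)
        rng = np.random.default_rng(23)
        perm = rng.permutation(data.normal.shape[1])
        shuffled = PairedExpressionData(
            tumor=data.tumor,
            normal=pd.DataFrame(
                data.normal.to_numpy()[:, perm],
                index=data.normal.index, columns=data.normal.columns,
            ),
        )
        broken = differential_expression(shuffled, fc_cut_log2=0.0, run_normality=False)
        down = list(truth.down_gene_ids)
        power_paired = (paired.set_index("gene").loc[down, "p_adj"] < 0.05).mean()
        power_broken = (broken.set_index("gene").loc[down, "p_adj"] < 0.05).mean()
        assert power_paired > power_broken + 0.3

    def test_filtered_genes_get_filtered_status(self):
        data = make_data([[1, 2, 3], [0, 5, 6]], [[1, 2, 3], [4, 5, 6]])
        res = differential_expression(data, run_normality=False)
        assert res.set_index("gene").loc["G1", "status"] == "filtered_zero"
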