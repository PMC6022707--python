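import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import famclust as fc
from famclust.core_data import StateError
from oracles import bh_oracle, partition_oracle


def _counts(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return fc.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), platform="count_like"
    )


class TestCpmNormalize:
    def test_sample_already_at_common_total_unchanged(self):
        vals = np.array([[4e5], [6e5]])
        out = fc.cpm_normalize(_counts(vals))
        np.testing.assert_allclose(out.values.to_numpy(), vals)

    def test_identical_proportions_align(self):
        vals = np.array([[100.0, 200.0], [300.0, 600.0]])
        out = fc.cpm_normalize(_counts(vals))
        np.testing.assert_allclose(out.values.iloc[:, 0], out.values.iloc[:, 1])

    def test_column_sums_equal_million(self, rng):
        vals = rng.poisson(50, size=(30, 8)).astype(float) + 1
        out = fc.cpm_normalize(_counts(vals))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(fc.ValidationError):
            fc.cpm_normalize(_counts([[0.0, 5.0]]))

    def test_log_scale_input_rejected(self):
        expr = fc.log2p1(_counts([[1.0, 2.0]]))
        with pytest.raises(StateError):
            fc.cpm_normalize(expr)


class TestBHAdjust:
    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fc.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_hand_stepup_examples(self):
        np.testing.assert_allclose(
            fc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )
        np.testing.assert_allclose(fc.bh_adjust([0.005, 0.5]), [0.01, 0.5], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(fc.ValidationError):
            fc.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(fc.bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_never_below_p_and_monotone(self, pvals):
        adj = fc.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDgeTwoGroup:
    def test_identical_groups_zero_fold_change(self, rng):
        vals = rng.poisson(40, size=(20, 4)).astype(float)
        dup = np.concatenate([vals, vals], axis=1)
        expr = _counts(dup, samples=[f"a{j}" for j in range(4)] + [f"b{j}" for j in range(4)])
        res = fc.dge_two_group(expr, [f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)])
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)

    @pytest.mark.parametrize("estimator", ["E1_parametric", "E2_rank"])
    def test_planted_shift_recovered_and_significant(self, estimator):
        spec = fc.CohortSpec(
            n_samples_per_cluster=(100,), n_genes=50, n_informative_genes=1,
            shift_matrix=np.full((1, 1), 2.0), baseline_log2_mean=7.0,
            cluster_log_hr=(0.0,), seed=31,
        )
        expr, _ = fc.simulate_expression(spec)
        normal = fc.simulate_normal_reference(spec, 100)
        combined = fc.ExpressionMatrix(
            pd.concat([expr.values, normal.values], axis=1), platform="count_like"
        )
        res = fc.dge_two_group(
            combined, list(expr.sample_ids), list(normal.sample_ids), estimator=estimator
        )
        g0 = res.table.iloc[0]
        assert 1.8 <= g0["log2fc"] <= 2.2
        assert g0["fdr"] < 0.05

    def test_overlapping_groups_rejected(self, rng):
        expr = _counts(rng.poisson(10, (5, 4)).astype(float))
        with pytest.raises(fc.ValidationError, match="overlap"):
            fc.dge_two_group(expr, ["s0", "s1"], ["s1", "s2"])

    def test_minimum_group_size(self, rng):
        expr = _counts(rng.poisson(10, (5, 4)).astype(float))
        with pytest.raises(fc.ValidationError, match="at least 2"):
            fc.dge_two_group(expr, ["s0"], ["s1", "s2"])

    def test_fdr_never_below_p(self, rng):
        expr = _counts(rng.poisson(30, (40, 12)).astype(float))
        res = fc.dge_two_group(expr, [f"s{j}" for j in range(6)],
                               [f"s{j}" for j in range(6, 12)])
        assert (res.table["fdr"] >= res.table["pvalue"] - 1e-12).all()


class TestThresholdDeg:
    def _res(self, rows):
        table = pd.DataFrame(rows, columns=["log2fc", "fdr"],
                             index=[f"g{i}" for i in range(len(rows))])
        table["pvalue"] = table["fdr"]
        table["mean_abundance"] = 1.0
        return fc.DGEResult("c", "E1_parametric", table)

    def test_boundary_fold_change_excluded(self):
        up, down = fc.threshold_deg(self._res([[1.0, 0.01]]))
        assert up == set() and down == set()

    @pytest.mark.parametrize(
        "lfc,fdr,in_up,in_down",
        [(1.5, 0.04, True, False), (-3.0, 0.06, False, False), (-1.2, 0.04, False, True)],
    )
    def test_rule_application(self, lfc, fdr, in_up, in_down):
        up, down = fc.threshold_deg(self._res([[lfc, fdr]]))
        assert ("g0" in up) is in_up
        assert ("g0" in down) is in_down

    def test_up_down_always_disjoint(self, rng):
        rows = np.column_stack([rng.normal(0, 2, 50), rng.uniform(0, 1, 50)])
        up, down = fc.threshold_deg(self._res(rows.tolist()))
        assert not up & down


class TestMethodConcordance:
    def _pair(self, fa, fb, fdr_a=None, fdr_b=None):
        genes = [f"g{i}" for i in range(len(fa))]

        def mk(f, fdr, est):
            t = pd.DataFrame({"log2fc": f, "pvalue": fdr if fdr is not None else 1.0,
                              "fdr": fdr if fdr is not None else 1.0,
                              "mean_abundance": 1.0}, index=genes)
            return fc.DGEResult("c", est, t)

        return mk(fa, fdr_a, "E1_parametric"), mk(fb, fdr_b, "E2_rank")

    def test_identical_results_perfect_agreement(self, rng):
        f = rng.normal(size=30)
        a, b = self._pair(f, f)
        rep = fc.method_concordance(a, b)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.frac_within_limits == pytest.approx(1.0)
        assert not rep.disagreeing_genes

    def test_plus_minus_one_diffs_limits(self):
        a, b = self._pair([1.0, 0.0], [0.0, 1.0])
        rep = fc.method_concordance(a, b)
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.loa_upper == pytest.approx(2.772, abs=1e-3)
        assert rep.loa_lower == pytest.approx(-2.772, abs=1e-3)

    def test_gaussian_noise_coverage_near_95_percent(self, rng):
        f = rng.normal(0, 2, size=1000)
        noise = rng.normal(0, 0.1, size=1000)
        a, b = self._pair(f, f + noise)
        rep = fc.method_concordance(a, b)
        assert rep.pearson_r > 0.99
        assert abs(rep.frac_within_limits - 0.95) <= 0.02

    def test_mismatched_gene_universe_rejected(self, rng):
        a, b = self._pair(rng.normal(size=5), rng.normal(size=5))
        b.table.index = pd.Index([f"h{i}" for i in range(5)])
        with pytest.raises(fc.ValidationError):
            fc.method_concordance(a, b)

    def test_disagreement_rule(self):
        # gene0: only E1 significant; gene1: both, opposite signs; gene2: agree
        fa = [2.0, 2.0, 2.0]
        fb = [2.0, -2.0, 2.0]
        fdr_a = [0.01, 0.01, 0.01]
        fdr_b = [0.5, 0.01, 0.01]
        a, b = self._pair(fa, fb, fdr_a, fdr_b)
        rep = fc.method_concordance(a, b)
        assert rep.disagreeing_genes == ["g0", "g1"]


class TestPartition:
    def test_identical_sets_all_shared(self):
        part = fc.partition_deg_sets({"c1": {"X", "Y"}, "c2": {"X", "Y"}})
        assert part.shared_in_all == {"X", "Y"}
        assert part.specific("c1") == set()

    def test_two_set_example(self):
        part = fc.partition_deg_sets({"c1": {"X", "Y"}, "c2": {"Y", "Z"}})
        assert part.shared_in_all == {"Y"}
        assert part.specific("c1") == {"X"}
        assert part.specific("c2") == {"Z"}

    def test_flagged_genes_excluded_first(self):
        part = fc.partition_deg_sets({"c1": {"X", "Y"}, "c2": {"Y"}}, excluded={"Y"})
        assert part.shared_in_all == set()
        assert part.specific("c1") == {"X"}

    def test_four_contrasts_match_membership_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        sets = {
            f"c{k}": set(rng.choice(genes, size=rng.integers(5, 25), replace=False))
            for k in range(4)
        }
        part = fc.partition_deg_sets(sets)
        assert part.regions == partition_oracle(sets)
        # disjoint and exhaustive
        all_genes = set().union(*sets.values())
        seen = set()
        for region in part.regions.values():
            assert not region & seen
            seen |= region
        assert seen == all_genes

    def test_single_contrast_rejected(self):
        with pytest.raises(fc.ValidationError):
            fc.partition_deg_sets({"c1": {"X"}})
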