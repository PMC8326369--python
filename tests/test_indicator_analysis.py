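import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import ecohof as eh
from ecohof import indicator_analysis as ia

from conftest import make_table


class TestAssignGroups:
    @pytest.mark.parametrize(
        "ph,band", [(4.0, "acid"), (5.2, "mid"), (6.5, "mid"), (7.0, "mid"), (7.5, "neutral")]
    )
    def test_band_boundaries(self, ph, band):
        meta = pd.DataFrame({"pH": [ph]}, index=["S1"])
        assert ia.assign_ph_groups(meta).loc["S1"] == band

    def test_accepts_sample_objects(self):
        samples = eh.generate_gradient(20, seed=1)
        groups = ia.assign_ph_groups(samples)
        assert len(groups) == 20
        assert set(groups.unique()) <= {"acid", "mid", "neutral"}


def brute_force_indval(counts, depths, labels):
    """Longhand group-equalized IndVal for tiny tables (independent oracle)."""
    counts = np.asarray(counts, dtype=float)
    rel = counts / np.asarray(depths, dtype=float)
    groups = sorted(set(labels))
    out = {}
    for i in range(counts.shape[0]):
        means = {
            g: np.mean([rel[i, j] for j, l in enumerate(labels) if l == g])
            for g in groups
        }
        for g in groups:
            A = means[g] / sum(means.values()) if sum(means.values()) else 0.0
            in_g = [j for j, l in enumerate(labels) if l == g]
            B = np.mean([counts[i, j] > 0 for j in in_g])
            out[(i, g)] = 100.0 * A * B
    return out


class TestIndval:
    def test_perfect_indicator_scores_100(self):
        table = make_table(
            [[5, 7, 0, 0], [1, 1, 1, 1]], ph=[4.0, 4.5, 6.0, 6.2])
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval(table, groups)
        top = res[(res.otu_id == "O1") & (res.group == "acid")].iloc[0]
        assert top["indval"] == pytest.approx(100.0)
        assert top["A"] == pytest.approx(1.0) and top["B"] == pytest.approx(1.0)

    def test_even_spread_across_two_groups_scores_50_each(self):
        # equal mean relative abundance and full occupancy in both groups
        table = make_table([[2, 2, 2, 2], [2, 2, 2, 2]], ph=[4.0, 4.5, 6.0, 6.2])
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval(table, groups)
        assert np.allclose(res["indval"], 50.0)

    def test_matches_brute_force_on_six_sample_table(self):
        counts = [[3, 0, 1, 0, 0, 0], [1, 2, 2, 4, 5, 0], [0, 0, 0, 6, 2, 3]]
        ph = [4.0, 4.3, 4.9, 6.1, 6.4, 6.9]
        table = make_table(counts)
        table.metadata["pH"] = ph
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval(table, groups).set_index(["otu_id", "group"])
        oracle = brute_force_indval(
            counts, table.depths.to_numpy(), list(groups))
        for (i, g), expected in oracle.items():
            got = res.loc[(f"O{i + 1}", g), "indval"]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_specificity_sums_to_one_per_otu(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.integers(0, 20, size=(10, 12)) + (rng.random((10, 12)) < 0.7))
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval(table, groups)
        sums = res.groupby("otu_id")["A"].sum()
        assert np.allclose(sums, 1.0)

    def test_invariant_to_relabeling_within_groups(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 30, size=(6, 8))
        ph = [4.0, 4.2, 4.4, 4.6, 7.5, 7.6, 7.7, 7.8]
        table = make_table(counts, ph=ph)
        groups = ia.assign_ph_groups(table.metadata)
        res1 = eh.indval(table, groups)
        # swap two samples within the acid group
        perm = [1, 0, 2, 3, 4, 5, 6, 7]
        table2 = make_table(counts[:, perm], ph=[ph[j] for j in perm])
        res2 = eh.indval(table2, ia.assign_ph_groups(table2.metadata))
        pd.testing.assert_frame_equal(res1, res2)

    def test_single_group_rejected(self):
        table = make_table([[1, 2]], ph=[6.0, 6.5])
        with pytest.raises(ValueError, match="2 groups"):
            eh.indval(table, ia.assign_ph_groups(table.metadata))


class TestPermutationTest:
    def test_perfect_indicator_is_significant(self):
        # perfect separation across 2 balanced groups of 6: only 2 of the
        # C(12,6) = 924 balanced relabelings reproduce it, so p << 0.05
        counts = np.zeros((1, 12), dtype=int)
        counts[0, :6] = [9, 8, 7, 9, 8, 7]
        # add a ubiquitous background OTU to avoid zero-depth samples
        counts2 = np.vstack([counts, np.ones(12, dtype=int)])
        table = make_table(counts2, ph=[4.0] * 6 + [6.0] * 6)
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval_permutation_test(table, groups, n_perm=999, seed=0)
        assert res.loc["O1", "p_value"] <= 0.01

    def test_constant_otu_has_p_one(self):
        table = make_table([[3, 3, 3, 3]], ph=[4.0, 4.5, 6.0, 6.5])
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval_permutation_test(table, groups, n_perm=99, seed=1)
        assert res.loc["O1", "p_value"] == pytest.approx(1.0)

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.poisson(4, size=(20, 12)) + 1)
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval_permutation_test(table, groups, n_perm=49, seed=2)
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()

    def test_null_p_values_are_uniform(self):
        # 200 OTUs with no group structure; KS test at alpha = 0.01
        rng = np.random.default_rng(11)
        counts = rng.poisson(5.0, size=(200, 30)) + 1
        ph = rng.uniform(3.63, 8.75, 30)  # random bands, no effect on counts
        table = make_table(counts, ph=ph)
        groups = ia.assign_ph_groups(table.metadata)
        res = eh.indval_permutation_test(table, groups, n_perm=199, seed=12)
        stat = kstest(res["p_value"], "uniform")
        assert stat.pvalue > 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        table = make_table(rng.poisson(3, size=(5, 10)) + 1)
        groups = ia.assign_ph_groups(table.metadata)
        r1 = eh.indval_permutation_test(table, groups, n_perm=99, seed=3)
        r2 = eh.indval_permutation_test(table, groups, n_perm=99, seed=3)
        pd.testing.assert_frame_equal(r1, r2)


class TestCrosstab:
    def _cross(self, band, ref_class, with_hit=True):
        from ecohof.response_classify import ResponseClassification
        from ecohof.sequence_match import MatchHit

        indicators = pd.DataFrame(
            {"group": [band], "indval": [90.0], "A": [0.9], "B": [1.0], "p_value": [0.001]},
            index=pd.Index(["Q1"], name="otu_id"),
        )
        best = {}
        if with_hit:
            best["Q1"] = MatchHit("Q1", "R1", 99.0, 400, 4, 0, 1, 400, 1, 400, 1e-50, 700.0)
        refs = {"R1": ResponseClassification("R1", ref_class, (4.5,))}
        return eh.crosstab_indicators_vs_reference(indicators, best, refs)

    def test_matching_band_agrees(self):
        out = self._cross("acid", "acid")
        assert out["agreement"] == pytest.approx(1.0)
        assert out["n_matched"] == 1

    def test_range_class_agrees_with_any_band_it_spans(self):
        assert self._cross("acid", "acid_to_mid")["agreement"] == pytest.approx(1.0)
        assert self._cross("neutral", "acid_to_mid")["agreement"] == pytest.approx(0.0)

    def test_unmatched_indicator_excluded_from_denominator(self):
        out = self._cross("acid", "acid", with_hit=False)
        assert out["n_matched"] == 0 and out["n_unmatched"] == 1
        assert np.isnan(out["agreement"])

    def test_end_to_end_agreement_on_shared_truths(self, e2e):
        groups = ia.assign_ph_groups(e2e.pair.query.metadata)
        indicators = eh.significant_indicators(
            e2e.pair.query, groups, n_perm=199, alpha=0.05, seed=7)
        assert len(indicators) > 20
        out = eh.crosstab_indicators_vs_reference(indicators, e2e.best_hits, e2e.classes)
        # query truths reuse reference truths, so inherited classes should
        # usually cover the observed band
        assert out["agreement"] >= 0.8
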