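"""Edge-wise group comparison, edge density and power analysis."""

import numpy as np
import pytest

from causalfc.errors import DegenerateDataError
from causalfc.graphs import RolledCFC
from causalfc.groups import (
    SubjectCFCSet,
    collect_edge_weights,
    edge_density,
    edgewise_comparison,
    required_sample_size,
    top_k_edges,
    welch_t_test,
)


def _cfc_set(rng, n_subj=6, labels=("A", "B", "C"), edge_weight=None):
    """Two-group set; edge_weight(group, subject index) -> weight of A->B."""
    entries = []
    for g in ("g1", "g2"):
        for s in range(n_subj):
            w = {}
            if edge_weight is not None:
                val = edge_weight(g, s)
                if val is not None:
                    w[("A", "B")] = val
            entries.append((f"{g}s{s}", g, RolledCFC(labels, w)))
    return SubjectCFCSet(tuple(entries))


class TestEdgeDensity:
    def test_empty_graph_zero(self):
        assert edge_density(RolledCFC(("A", "B"))) == 0.0

    def test_full_graph_one(self):
        labels = ("A", "B", "C")
        w = {(u, v): 1.0 for u in labels for v in labels}
        assert edge_density(RolledCFC(labels, w)) == 1.0
        w_noself = {(u, v): 1.0 for u in labels for v in labels if u != v}
        assert edge_density(RolledCFC(labels, w_noself), include_self_loops=False) == 1.0

    def test_157_edges_of_116_regions(self, rng):
        labels = tuple(f"R{i}" for i in range(116))
        pairs = [(a, b) for a in labels for b in labels]
        pick = rng.choice(len(pairs), 157, replace=False)
        g = RolledCFC(labels, {pairs[k]: 1.0 for k in pick})
        assert edge_density(g) == pytest.approx(157 / 13456)

    def test_bounds(self, rng):
        for _ in range(5):
            labels = ("A", "B", "C", "D")
            pairs = [(a, b) for a in labels for b in labels]
            k = rng.integers(0, len(pairs))
            pick = rng.choice(len(pairs), k, replace=False)
            d = edge_density(RolledCFC(labels, {pairs[i]: 1.0 for i in pick}))
            assert 0 <= d <= 1


class TestCollectEdgeWeights:
    def test_absent_edge_gives_zero_vectors(self, rng):
        cfcs = _cfc_set(rng)
        x, y = collect_edge_weights(cfcs, ("A", "C"), ("g1", "g2"))
        assert np.all(x == 0) and np.all(y == 0)
        assert len(x) == len(y) == 6

    def test_present_everywhere(self, rng):
        cfcs = _cfc_set(rng, n_subj=3, edge_weight=lambda g, s: 1.0 + s)
        x, y = collect_edge_weights(cfcs, ("A", "B"), ("g1", "g2"))
        assert list(x) == [1.0, 2.0, 3.0]
        assert list(y) == [1.0, 2.0, 3.0]

    def test_mixed_presence_zeros_in_stable_order(self, rng):
        cfcs = _cfc_set(
            rng, n_subj=3, edge_weight=lambda g, s: 2.0 if s == 1 else None
        )
        x, _ = collect_edge_weights(cfcs, ("A", "B"), ("g1", "g2"))
        assert list(x) == [0.0, 2.0, 0.0]

    def test_unknown_region_rejected(self, rng):
        with pytest.raises(KeyError, match="unknown region"):
            collect_edge_weights(_cfc_set(rng), ("A", "Z"), ("g1", "g2"))

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(KeyError, match="unknown group"):
            collect_edge_weights(_cfc_set(rng), ("A", "B"), ("g1", "g9"))


class TestWelch:
    def test_identical_samples_give_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p = welch_t_test(x, x, "greater")
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_reference_values(self):
        """Cross-checked against the statsmodels unequal-variance t-test."""
        sm = pytest.importorskip("statsmodels.stats.weightstats")
        x = [2.1, 2.5, 2.3, 2.7]
        y = [1.1, 1.4, 1.2, 1.5]
        t, df, p = welch_t_test(x, y, "greater")
        t_ref, p_ref, df_ref = sm.ttest_ind(
            np.array(x), np.array(y), usevar="unequal", alternative="larger"
        )
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert df == pytest.approx(df_ref, rel=1e-10)

    def test_welch_satterthwaite_df_formula(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(scale=3.0, size=45)
        _, df, _ = welch_t_test(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        num = (vx / 15 + vy / 45) ** 2
        den = (vx / 15) ** 2 / 14 + (vy / 45) ** 2 / 44
        assert df == pytest.approx(num / den)

    def test_both_constant_equal_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="constant and equal"):
            welch_t_test([1.0, 1.0], [1.0, 1.0])

    def test_both_constant_unequal_p_limits(self):
        t, _, p = welch_t_test([2.0, 2.0], [1.0, 1.0], "greater")
        assert t == np.inf and p == 0.0
        t, _, p = welch_t_test([1.0, 1.0], [2.0, 2.0], "greater")
        assert p == 1.0

    def test_type_one_error_calibrated(self, rng):
        """Null calibration with unequal variances (quick version; the
        5000-replicate sweep runs in the acceptance suite)."""
        rej = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=15)
            y = rng.normal(scale=3.0, size=45)
            rej += welch_t_test(x, y, "greater")[2] < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.02)


class TestEdgewiseComparison:
    def test_boosted_edge_ranks_first(self, rng):
        cfcs = _cfc_set(
            rng,
            n_subj=30,
            edge_weight=lambda g, s: rng.normal(loc=2.0 if g == "g2" else 0.0),
        )
        table = edgewise_comparison(cfcs, "g1", "g2", direction="g2>g1")
        assert (table.iloc[0]["source"], table.iloc[0]["target"]) == ("A", "B")
        assert table.iloc[0]["p"] < 0.01

    def test_no_detected_edges_gives_empty_table(self, rng):
        cfcs = _cfc_set(rng)
        table = edgewise_comparison(cfcs, "g1", "g2")
        assert len(table) == 0
        assert list(table.columns)[:2] == ["source", "target"]

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy import stats

        labels = tuple(f"R{i}" for i in range(12))
        pairs = [(a, b) for a in labels for b in labels]
        entries = []
        for g in ("g1", "g2"):
            for s in range(20):
                w = {pair: rng.normal() for pair in pairs}
                entries.append((f"{g}{s}", g, RolledCFC(labels, w)))
        table = edgewise_comparison(SubjectCFCSet(tuple(entries)), "g1", "g2")
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_sorted_ascending_with_lexicographic_ties(self, rng):
        cfcs = _cfc_set(rng, n_subj=10, edge_weight=lambda g, s: rng.normal())
        table = edgewise_comparison(cfcs, "g1", "g2")
        assert list(table["p"]) == sorted(table["p"])

    def test_needs_two_subjects_per_group(self, rng):
        entries = (
            ("a", "g1", RolledCFC(("A", "B"), {("A", "B"): 1.0})),
            ("b", "g2", RolledCFC(("A", "B"), {("A", "B"): 1.0})),
            ("c", "g2", RolledCFC(("A", "B"), {("A", "B"): 2.0})),
        )
        with pytest.raises(ValueError, match="2 subjects"):
            edgewise_comparison(SubjectCFCSet(entries), "g1", "g2")


class TestTopK:
    def test_short_table_returned_whole(self, rng):
        cfcs = _cfc_set(rng, n_subj=4, edge_weight=lambda g, s: rng.normal())
        table = edgewise_comparison(cfcs, "g1", "g2")
        assert len(top_k_edges(table, 10)) == len(table) <= 10

    def test_k_zero_empty(self, rng):
        cfcs = _cfc_set(rng, n_subj=4, edge_weight=lambda g, s: rng.normal())
        assert len(top_k_edges(edgewise_comparison(cfcs, "g1", "g2"), 0)) == 0


class TestRequiredSampleSize:
    def test_reproduces_published_family_wise_design(self):
        res = required_sample_size(0.25, 1475, 0.05, 0.95, n_groups=3)
        assert abs(res.n_per_group - 2117) <= 1
        assert abs(res.n_total - 6352) <= 1

    def test_classical_single_test_value(self):
        """One test at alpha .05, power .95, d = .25: the textbook ~417."""
        res = required_sample_size(0.25, 1, 0.05, 0.95, n_groups=2)
        assert res.n_per_group == 417

    def test_tenfold_effect_shrinks_n_roughly_hundredfold(self):
        big = required_sample_size(0.25, 1475, 0.05, 0.95, n_groups=3)
        small = required_sample_size(2.5, 1475, 0.05, 0.95, n_groups=3)
        assert small.n_per_group < big.n_per_group / 50

    def test_monotone_in_effect_size_and_tests(self):
        ds = [0.2, 0.4, 0.8]
        ns = [required_sample_size(d, 100, n_groups=2).n_per_group for d in ds]
        assert ns == sorted(ns, reverse=True)
        ms = [1, 100, 10000]
        nt = [required_sample_size(0.3, m, n_groups=2).n_per_group for m in ms]
        assert nt == sorted(nt)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(-0.2, 10)
        with pytest.raises(ValueError):
            required_sample_size(0.2, 10, fwer=1.5)
        with pytest.raises(ValueError):
            required_sample_size(0.2, 10, n_groups=1)
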