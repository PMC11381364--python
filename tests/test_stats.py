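"""Normalization, EPS calling, overlap Fisher test, junction-length comparison."""

import numpy as np
import pytest

from uindel import (
    SamplePopulation,
    bh_adjust,
    eps_call,
    jl_bin_percentages,
    jl_compare,
    normalize_counts,
    overlap_fisher,
    single_case_t,
)
from uindel.errors import (
    EmptyPopulation,
    InvalidSets,
    TooFewControls,
    TooFewSamples,
)

from oracles import bh_stepup, hypergeom_tail


def make_pop(stop_counts, sample_id="s", condition="control", jl_bins=None):
    stop_counts = np.asarray(stop_counts, dtype=np.int64)
    n_rows = len(stop_counts)
    if jl_bins is None:
        jl_bins = np.zeros((n_rows, 4), dtype=np.int64)
        jl_bins[:, 0] = stop_counts
    return SamplePopulation(
        sample_id=sample_id,
        condition=condition,
        n_es=n_rows - 1,
        stop_counts_raw=stop_counts,
        jl_bins=np.asarray(jl_bins),
        total_standard=int(stop_counts.sum()),
        total_nonstandard=0,
    )


class TestNormalization:
    def test_proportional_scaling(self):
        pop = make_pop([3, 0, 0, 0, 1])
        normalize_counts(pop)
        assert pop.stop_counts_norm.tolist() == [75_000, 0, 0, 0, 25_000]

    def test_already_at_total_unchanged(self):
        pop = make_pop([60_000, 40_000, 0])
        normalize_counts(pop)
        assert pop.stop_counts_norm.tolist() == [60_000, 40_000, 0]

    def test_single_class(self):
        pop = make_pop([0, 0, 7])
        normalize_counts(pop)
        assert pop.stop_counts_norm.tolist() == [0, 0, 100_000]

    def test_values_stay_real(self):
        pop = make_pop([1, 1, 1])
        normalize_counts(pop)
        assert pop.stop_counts_norm == pytest.approx([100_000 / 3] * 3)

    def test_empty_population_raises(self):
        with pytest.raises(EmptyPopulation):
            normalize_counts(make_pop([0, 0, 0]))


class TestSingleCaseT:
    def test_matches_manual_formula(self):
        control = np.array([[10.0], [12.0], [11.0], [9.0]])
        x = np.array([20.0])
        t, p = single_case_t(x, control)
        m = 4
        sd = control.std(ddof=1)
        expected_t = (20 - 10.5) / (sd * np.sqrt(1 + 1 / m))
        assert t[0] == pytest.approx(expected_t)
        from scipy.stats import t as tdist

        assert p[0] == pytest.approx(tdist.sf(expected_t, df=m - 1))

    def test_case_equal_to_constant_controls_is_null(self):
        t, p = single_case_t(np.array([5.0]), np.full((3, 1), 5.0))
        assert t[0] == 0.0
        assert p[0] == pytest.approx(0.5)


class TestEpsCall:
    def _experiment(self, rng, n_rows=61, planted=None, effect=0.0, total=50_000):
        """Two induced + seven controls with optional planted overrepresentation."""
        base = np.full(n_rows, 1 / n_rows)
        pops = {"induced": [], "control": []}
        for cond, n in (("induced", 2), ("control", 7)):
            p = base.copy()
            if planted is not None and cond == "induced":
                p[list(planted)] += effect
                p /= p.sum()
            for i in range(n):
                counts = rng.multinomial(total, p)
                pops[cond].append(make_pop(counts, f"{cond}_{i}", cond))
        return pops["induced"], pops["control"]

    def test_strong_planted_site_flagged(self, rng):
        induced, controls = self._experiment(rng, planted=[7], effect=0.08)
        res = eps_call(induced, controls)
        assert 7 in res.eps_flags
        # the planted site massively dominates: nothing else should co-flag
        assert res.eps_flags == {7}

    def test_no_effect_no_flags(self):
        counts = np.tile(np.arange(1, 11) * 100, (1, 1))[0]
        induced = [make_pop(counts, f"i{k}", "induced") for k in range(2)]
        controls = [make_pop(counts, f"c{k}", "control") for k in range(4)]
        res = eps_call(induced, controls)
        assert res.eps_flags == set()

    def test_underrepresented_site_never_flagged(self, rng):
        induced, controls = self._experiment(rng)
        # force induced far below controls at row 3
        for pop in induced:
            pop.stop_counts_raw[3] = 0
            pop.stop_counts_norm = None
        res = eps_call(induced, controls)
        assert 3 not in res.eps_flags
        assert (res.direction[:, 3] < 0).all()

    def test_requires_both_replicates_significant(self, rng):
        induced, controls = self._experiment(rng)
        induced[0].stop_counts_raw[5] += 40_000  # only replicate 1 elevated
        induced[0].stop_counts_norm = None
        res = eps_call(induced, controls)
        assert 5 not in res.eps_flags
        assert res.p_adj[0, 5] < 0.05 < res.p_adj[1, 5]

    def test_too_few_controls(self):
        pops = [make_pop([5, 5], f"p{i}") for i in range(3)]
        with pytest.raises(TooFewControls):
            eps_call(pops[:2], pops[2:])

    def test_needs_exactly_two_induced(self):
        pops = [make_pop([5, 5], f"p{i}") for i in range(4)]
        with pytest.raises(TooFewSamples):
            eps_call(pops[:1], pops[1:])

    def test_zero_variance_rows_are_smoothed_not_infinite(self):
        # controls identical -> sd 0 at every row; smoothing keeps p finite
        controls = [make_pop([100, 100, 100], f"c{i}") for i in range(3)]
        induced = [make_pop([150, 100, 50], f"i{i}", "induced") for i in range(2)]
        res = eps_call(induced, controls)
        assert np.isfinite(res.p_raw).all()


class TestBHAdjust:
    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 80))
            p = rng.random(n)
            np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), rtol=1e-12)

    def test_ties_and_duplicates(self):
        p = [0.02, 0.02, 0.5, 0.5, 1.0]
        np.testing.assert_allclose(bh_adjust(p), bh_stepup(p))


class TestOverlapFisher:
    def test_identical_sets_closed_form(self):
        res = overlap_fisher(set(range(1, 6)), set(range(1, 6)), 20)
        assert res.p_value == pytest.approx(1 / 15504, rel=1e-9)
        assert (res.both, res.a_only, res.b_only, res.neither) == (5, 0, 0, 15)

    def test_empty_set_p_one(self):
        res = overlap_fisher(set(), {1, 2, 3}, 20)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_sets_p_one(self):
        res = overlap_fisher(set(range(1, 11)), set(range(11, 21)), 20)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 201))
            ka = int(rng.integers(0, n + 1))
            kb = int(rng.integers(0, n + 1))
            sites = rng.permutation(np.arange(1, n + 1))
            a = set(sites[:ka].tolist())
            b_sites = rng.permutation(np.arange(1, n + 1))
            b = set(b_sites[:kb].tolist())
            res = overlap_fisher(a, b, n)
            expected = hypergeom_tail(len(a & b), ka, kb, n)
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_sites_outside_universe_rejected(self):
        with pytest.raises(InvalidSets):
            overlap_fisher({1, 25}, {2}, 20)

    def test_two_sided_available(self):
        res = overlap_fisher({1, 2, 3}, {1, 2, 4}, 10, alternative="two-sided")
        assert res.alternative == "two-sided"
        assert 0 < res.p_value <= 1


class TestJlBinPercentages:
    def test_direct_proportions(self):
        jl = np.zeros((3, 4), dtype=int)
        jl[1] = [50, 30, 10, 10]
        pop = make_pop([0, 100, 0], jl_bins=jl)
        df = jl_bin_percentages(pop)
        assert df["es"].tolist() == [1]  # empty stop sites emit no row
        row = df.iloc[0]
        assert [row[f"pct_{b}"] for b in ("0", "1-10", "11-20", ">20")] == [
            50.0,
            30.0,
            10.0,
            10.0,
        ]

    def test_all_jl_zero(self):
        pop = make_pop([10, 5])
        df = jl_bin_percentages(pop)
        assert (df["pct_0"] == 100.0).all()
        assert (df[["pct_1-10", "pct_11-20", "pct_>20"]] == 0).all().all()

    def test_rows_sum_to_100(self, rng):
        jl = rng.integers(0, 50, size=(5, 4))
        pop = make_pop(jl.sum(axis=1), jl_bins=jl)
        df = jl_bin_percentages(pop)
        sums = df[[f"pct_{b}" for b in ("0", "1-10", "11-20", ">20")]].sum(axis=1)
        assert sums.to_numpy() == pytest.approx(100.0)


class TestJlCompare:
    def _pop_with_jl0(self, pct0, n=1000, sample_id="s", condition="control", rows=5):
        jl = np.zeros((rows, 4), dtype=int)
        for r in range(rows):
            jl[r, 0] = round(n * pct0 / 100) if r == 2 else n // 2
            jl[r, 3] = n - jl[r, 0]
        return make_pop(jl.sum(axis=1), sample_id=sample_id, condition=condition, jl_bins=jl)

    def test_shifted_percentages_flagged_with_direction(self):
        controls = [self._pop_with_jl0(p, sample_id=f"c{i}") for i, p in enumerate((10, 12, 11))]
        induced = [
            self._pop_with_jl0(p, sample_id=f"i{i}", condition="induced")
            for i, p in enumerate((30, 29))
        ]
        df = jl_compare(induced, controls)
        hit = df[(df.es == 2) & (df["bin"] == "0")].iloc[0]
        assert hit.significant
        assert hit.direction == "induced>control"
        # complementary shift in the >20 bin, opposite sign
        hit20 = df[(df.es == 2) & (df["bin"] == ">20")].iloc[0]
        assert hit20.significant
        assert hit20.direction == "induced<control"

    def test_identical_percentages_nothing_flagged(self):
        pops = [self._pop_with_jl0(10, sample_id=f"p{i}") for i in range(5)]
        df = jl_compare(pops[:2], pops[2:])
        assert not df.significant.any()

    def test_too_few_samples(self):
        pops = [self._pop_with_jl0(10, sample_id=f"p{i}") for i in range(3)]
        with pytest.raises(TooFewSamples):
            jl_compare(pops[:1], pops[1:])
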