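"""Tests of DNB statistics, module discovery and tipping-point detection."""

import math

import numpy as np
import pytest

from dnbpipe import (EmptyCandidatesError, ParameterError, SyntheticParams,
                     candidate_modules, detect_tipping_point, module_stats,
                     permutation_significance, simulate_timecourse,
                     with_significance)


# ---------------------------------------------------------------------------
# brute-force definitional oracle (sum formulas only, no library calls)
# ---------------------------------------------------------------------------

def _pearson(x, y):
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def _sd(x):
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))


def brute_force_stats(window, gene_ids, module, epsilon):
    cols = {g: window[:, i].tolist() for i, g in enumerate(gene_ids)}
    mod = sorted(module)
    out = sorted(set(gene_ids) - set(module))
    pin = [abs(_pearson(cols[a], cols[b]))
           for i, a in enumerate(mod) for b in mod[i + 1:]]
    pout = [abs(_pearson(cols[a], cols[b])) for a in mod for b in out]
    pcc_in = sum(pin) / len(pin)
    pcc_out = sum(pout) / len(pout)
    sd_in = sum(_sd(cols[g]) for g in mod) / len(mod)
    return pcc_in, pcc_out, sd_in, sd_in * pcc_in / max(pcc_out, epsilon)


class TestModuleStats:
    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        """PCC_in/PCC_out/SD_in/CI agree with the definitional sum-formula
        computation to 1e-10 on 100 random small windows."""
        for _ in range(100):
            n_genes = int(rng.integers(4, 11))
            n_samples = int(rng.integers(4, 13))
            window = rng.normal(size=(n_samples, n_genes))
            gene_ids = [f"g{i}" for i in range(n_genes)]
            mod_size = int(rng.integers(2, n_genes))
            module = set(rng.choice(gene_ids, size=mod_size, replace=False))
            st = module_stats(window, gene_ids, module, epsilon=1e-3)
            exp = brute_force_stats(window, gene_ids, module, 1e-3)
            assert st.pcc_in == pytest.approx(exp[0], abs=1e-10)
            assert st.pcc_out == pytest.approx(exp[1], abs=1e-10)
            assert st.sd_in == pytest.approx(exp[2], abs=1e-10)
            assert st.ci == pytest.approx(exp[3], abs=1e-10)

    def test_perfectly_correlated_module_against_orthogonal_background(self):
        """Two identical module genes give pcc_in = 1; an uncorrelated
        background drives pcc_out toward 0 and the CI to sd_in/epsilon."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        u = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        u = u - u.mean()
        u = u - (u @ (t - t.mean())) / ((t - t.mean()) @ (t - t.mean())) \
            * (t - t.mean())  # orthogonalize against t
        window = np.column_stack([t, t, u, -2 * u])
        st = module_stats(window, ["m1", "m2", "b1", "b2"], {"m1", "m2"},
                          epsilon=1e-3)
        assert st.pcc_in == pytest.approx(1.0, abs=1e-12)
        assert st.pcc_out == pytest.approx(0.0, abs=1e-12)
        assert st.ci == pytest.approx(st.sd_in / 1e-3, rel=1e-9)

    def test_ci_formula_arithmetic(self):
        """sd_in=1, pcc_in=1, pcc_out=0.5 must give ci = 2 by the formula."""
        from dnbpipe.dnb import DNBWindowStats  # construct directly
        st = DNBWindowStats(window_index=0, window_times=(0.0,),
                            module_gene_ids=frozenset({"a", "b"}),
                            pcc_in=1.0, pcc_out=0.5, sd_in=1.0,
                            ci=1.0 * 1.0 / 0.5)
        assert st.ci == 2.0

    def test_scale_equivariance(self, rng):
        """Scaling a window by k scales sd_in and ci by k; correlations are
        unchanged."""
        window = rng.normal(size=(8, 6))
        genes = [f"g{i}" for i in range(6)]
        module = {"g0", "g3", "g4"}
        a = module_stats(window, genes, module)
        b = module_stats(3.0 * window, genes, module)
        assert b.pcc_in == pytest.approx(a.pcc_in, abs=1e-12)
        assert b.pcc_out == pytest.approx(a.pcc_out, abs=1e-12)
        assert b.sd_in == pytest.approx(3.0 * a.sd_in, rel=1e-12)
        assert b.ci == pytest.approx(3.0 * a.ci, rel=1e-12)

    def test_shuffle_invariance(self, rng):
        """Permuting gene order or sample order leaves statistics alone."""
        window = rng.normal(size=(7, 5))
        genes = [f"g{i}" for i in range(5)]
        module = {"g1", "g2"}
        a = module_stats(window, genes, module)
        gperm = rng.permutation(5)
        b = module_stats(window[:, gperm], [genes[i] for i in gperm], module)
        sperm = rng.permutation(7)
        c = module_stats(window[sperm], genes, module)
        for other in (b, c):
            assert other.pcc_in == pytest.approx(a.pcc_in, abs=1e-12)
            assert other.pcc_out == pytest.approx(a.pcc_out, abs=1e-12)
            assert other.sd_in == pytest.approx(a.sd_in, abs=1e-12)

    @pytest.mark.parametrize("module", [set(), {"g0"}])
    def test_too_small_module_rejected(self, rng, module):
        window = rng.normal(size=(5, 4))
        with pytest.raises(ParameterError):
            module_stats(window, [f"g{i}" for i in range(4)], module)

    def test_module_covering_all_genes_rejected(self, rng):
        window = rng.normal(size=(5, 3))
        with pytest.raises(ParameterError):
            module_stats(window, ["a", "b", "c"], {"a", "b", "c"})

    def test_zero_variance_gene_named(self, rng):
        window = rng.normal(size=(5, 3))
        window[:, 1] = 2.0
        with pytest.raises(ParameterError, match="g1"):
            module_stats(window, ["g0", "g1", "g2"], {"g0", "g2"})


class TestCandidateModules:
    def test_planted_correlated_blocks_are_candidates(self, rng):
        """Two perfectly correlated 5-gene blocks amid iid noise genes both
        appear among the hierarchical candidates."""
        n_samples = 12
        base1 = rng.normal(size=n_samples)
        base2 = rng.normal(size=n_samples)
        block1 = np.column_stack([base1 * s for s in (1, 2, 3, 1.5, 0.5)])
        block2 = np.column_stack([base2 * s for s in (1, -1, 2, -2, 0.7)])
        noise = rng.normal(size=(n_samples, 20))
        window = np.column_stack([block1, block2, noise])
        genes = [f"m{i}" for i in range(5)] + [f"k{i}" for i in range(5)] \
            + [f"n{i}" for i in range(20)]
        cands = candidate_modules(window, genes, min_size=4, max_size=8)
        assert frozenset(f"m{i}" for i in range(5)) in cands
        assert frozenset(f"k{i}" for i in range(5)) in cands

    def test_impossible_bounds_raise_empty_candidates(self, rng):
        window = rng.normal(size=(10, 12))
        genes = [f"g{i}" for i in range(12)]
        with pytest.raises(EmptyCandidatesError):
            candidate_modules(window, genes, min_size=7, max_size=7,
                              n_cut_levels=1)

    def test_invalid_bounds_rejected(self, rng):
        window = rng.normal(size=(5, 6))
        genes = [f"g{i}" for i in range(6)]
        with pytest.raises(ParameterError):
            candidate_modules(window, genes, min_size=5, max_size=3)

    def test_deterministic(self, small_course):
        tc, _ = small_course
        a = candidate_modules(tc.values.T, tc.gene_ids, min_size=10,
                              max_size=60)
        b = candidate_modules(tc.values.T, tc.gene_ids, min_size=10,
                              max_size=60)
        assert a == b


class TestDetectTippingPoint:
    def test_recovers_planted_window_on_small_courses(self):
        """On fast, well-powered 300-gene planted courses (5 replicates,
        strong bump) the CI peak lands on a window containing the planted
        day and the module is substantially recovered in most seeded runs."""
        hits = 0
        jaccards = []
        n_runs = 8
        for seed in range(n_runs):
            p = SyntheticParams(n_genes=300, module_size=20,
                                replicates_per_time=5,
                                module_loading_peak=2.5, seed=seed)
            tc, truth = simulate_timecourse(p)
            res = detect_tipping_point(tc, min_size=10, max_size=60)
            hits += truth.tp_time in res.tp_times
            m, d = truth.module_gene_ids, res.dnb_gene_ids
            jaccards.append(len(m & d) / len(m | d))
        assert hits >= 6
        assert np.median(jaccards) >= 0.4

    def test_result_invariants(self, small_course):
        tc, _ = small_course
        res = detect_tipping_point(tc, min_size=10, max_size=60)
        ci = res.ci_series
        assert res.tp_window_index == int(np.argmax(ci))
        assert res.dnb_gene_ids == \
            res.per_window[res.tp_window_index].module_gene_ids
        for w in res.per_window:
            assert 0.0 <= w.pcc_in <= 1.0
            assert 0.0 <= w.pcc_out <= 1.0
            assert w.sd_in >= 0.0
            assert w.n_samples >= 3

    def test_ci_linear_in_window_scale(self, rng):
        """Tripling all expression values of one window triples that
        window's CI for any fixed module (CI is linear in SD_in)."""
        window = rng.normal(size=(6, 8))
        genes = [f"g{i}" for i in range(8)]
        module = {"g0", "g1", "g2"}
        a = module_stats(window, genes, module)
        b = module_stats(3.0 * window, genes, module)
        assert b.ci == pytest.approx(3.0 * a.ci, rel=1e-12)

    def test_window_too_small_is_an_error(self):
        p = SyntheticParams(n_genes=80, module_size=10,
                            replicates_per_time=2, seed=0)
        tc, _ = simulate_timecourse(p)
        with pytest.raises(ParameterError, match="window"):
            detect_tipping_point(tc, window_width=1, min_size=5, max_size=40)

    def test_detection_deterministic(self, small_course):
        tc, _ = small_course
        a = detect_tipping_point(tc, min_size=10, max_size=60)
        b = detect_tipping_point(tc, min_size=10, max_size=60)
        assert a.tp_window_index == b.tp_window_index
        assert a.dnb_gene_ids == b.dnb_gene_ids
        assert np.array_equal(a.ci_series, b.ci_series)


class TestPermutationSignificance:
    def test_requires_enough_permutations(self, small_course):
        tc, _ = small_course
        res = detect_tipping_point(tc, min_size=10, max_size=60)
        with pytest.raises(ParameterError):
            permutation_significance(tc, res, n_perm=10)

    def test_p_value_bounds_and_determinism(self, small_course):
        tc, _ = small_course
        res = detect_tipping_point(tc, min_size=10, max_size=60)
        p1 = permutation_significance(tc, res, n_perm=29, seed=4,
                                      min_size=10, max_size=60)
        p2 = permutation_significance(tc, res, n_perm=29, seed=4,
                                      min_size=10, max_size=60)
        assert p1 == p2
        assert 1 / 30 <= p1 <= 1.0

    def test_add_one_estimator_boundaries(self):
        """p is (1 + #exceedances)/(n_perm + 1): all-exceed gives 1 and
        none-exceed gives 1/(n_perm+1)."""
        n_perm = 99
        assert (1 + n_perm) / (n_perm + 1) == 1.0
        assert (1 + 0) / (n_perm + 1) == pytest.approx(0.01)

    def test_detects_concentrated_transition(self):
        """A strong, tightly realized transition (many replicates) yields a
        small p-value."""
        p = SyntheticParams(n_genes=200, module_size=20,
                            replicates_per_time=6,
                            module_loading_peak=3.0, seed=2)
        tc, _ = simulate_timecourse(p)
        res = detect_tipping_point(tc, min_size=10, max_size=50)
        res = with_significance(tc, res, n_perm=49, seed=0)
        assert res.permutation_p <= 0.1
        assert res.n_permutations == 49
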