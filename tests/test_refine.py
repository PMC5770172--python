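"""Jensen-Shannon divergence matrix and annealed subset selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from pomcal import density, refine, synthetic
from pomcal.refine import (JSD_MAX, PopulationOfModels, RefinementConfig,
                           anneal_refine, divergence, jsd)


def sample_from_kde(est, n, rng):
    """Draws from a fitted KDE, mapped back to raw biomarker space."""
    idx = rng.integers(est.n, size=n)
    Z = est.points[idx] + rng.normal(size=(n, est.dim)) * np.sqrt(est.H)
    Y = Z.copy()
    Y[:, est.log_dims] = np.exp(Y[:, est.log_dims])
    return Y


class TestJsd:
    def test_identical_densities(self):
        p = norm.pdf(np.linspace(-4, 4, 200))
        assert jsd(p, p.copy(), 8 / 199) == 0.0

    def test_disjoint_supports_attain_maximum(self):
        p = np.zeros(100)
        q = np.zeros(100)
        p[:50] = 1.0
        q[50:] = 1.0
        assert jsd(p, q, 0.01) == pytest.approx(JSD_MAX, abs=1e-6)

    def test_symmetry_exact(self, rng):
        p = rng.uniform(0.1, 1, 64)
        q = rng.uniform(0.1, 1, 64)
        assert jsd(p, q, 0.1) == jsd(q, p, 0.1)

    def test_gaussians_match_quadrature_oracle(self):
        """JSD between N(0,1) and N(1,1) against adaptive quadrature."""
        f, g = norm(0, 1).pdf, norm(1, 1).pdf

        def integrand(x):
            p, q = f(x), g(x)
            m = 0.5 * (p + q)
            val = 0.0
            if p > 0:
                val += 0.5 * p * np.log(p / m)
            if q > 0:
                val += 0.5 * q * np.log(q / m)
            return val

        oracle = np.sqrt(quad(integrand, -10, 11, limit=200)[0])
        grid = np.linspace(-10, 11, 4001)
        ours = jsd(f(grid), g(grid), grid[1] - grid[0])
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.ones(10), np.ones(11))

    def test_bounds(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 50)
            q = rng.uniform(0, 1, 50)
            v = jsd(p + 1e-12, q + 1e-12, 0.1)
            assert 0.0 <= v <= JSD_MAX + 1e-12


class TestDivergence:
    def test_pom_equal_to_data_gives_zero(self, sr_table):
        est = density.fit_density(sr_table)
        pom = PopulationOfModels(theta=np.zeros((len(sr_table), 1)),
                                 biomarkers=sr_table.to_numpy())
        _, rho = divergence(pom, est, bins=64)
        assert rho == pytest.approx(0.0, abs=1e-10)

    def test_rho_hat_never_exceeds_rho(self, sr_table, rng):
        est = density.fit_density(sr_table)
        Y = sample_from_kde(est, 200, rng) * rng.uniform(0.9, 1.1, size=7)
        pom = PopulationOfModels(theta=np.zeros((200, 1)), biomarkers=Y)
        _, rho = divergence(pom, est, bins=64)
        _, rho_hat = divergence(pom, est, mode="rho_hat", bins=64)
        assert rho_hat <= rho + 1e-12

    def test_matrix_shape_and_symmetry(self, sr_table, rng):
        est = density.fit_density(sr_table)
        pom = PopulationOfModels(theta=np.zeros((100, 1)),
                                 biomarkers=sample_from_kde(est, 100, rng))
        m, _ = divergence(pom, est, bins=48)
        assert m.P.shape == (7, 7)
        assert np.array_equal(m.P, m.P.T)
        assert np.all(m.P >= 0) and np.all(m.P <= JSD_MAX + 1e-12)

    def test_rho_hat_zeroes_dvdtmax_row(self, sr_table, rng):
        est = density.fit_density(sr_table)
        pom = PopulationOfModels(theta=np.zeros((100, 1)),
                                 biomarkers=sample_from_kde(est, 100, rng))
        m, _ = divergence(pom, est, mode="rho_hat", bins=48)
        k = refine.DVDTMAX_INDEX
        off = np.delete(m.P[k], k)
        assert np.all(off == 0)
        assert m.P[k, k] > 0

    def test_kde_sample_beats_uniform_sample(self, sr_table, rng):
        """A POM drawn from the data KDE is closer to the data (lower rho)
        than an equal-size uniform-over-ranges sample (paired repeats)."""
        est = density.fit_density(sr_table)
        lo = sr_table.min().to_numpy()
        hi = sr_table.max().to_numpy()
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(100 + rep)
            good = sample_from_kde(est, 500, r)
            unif = r.uniform(lo, hi, size=(500, 7))
            unif[:, 1] = np.maximum(unif[:, 1], unif[:, 0] + 1e-6)
            unif[:, 2] = np.maximum(unif[:, 2], unif[:, 1] + 1e-6)
            _, rho_g = divergence(PopulationOfModels(
                theta=np.zeros((500, 1)), biomarkers=good), est, bins=48)
            _, rho_u = divergence(PopulationOfModels(
                theta=np.zeros((500, 1)), biomarkers=unif), est, bins=48)
            wins += rho_g < rho_u
        assert wins >= 0.95 * n_rep

    def test_degenerate_population_rejected(self, sr_table):
        est = density.fit_density(sr_table)
        Y = np.tile(sr_table.iloc[0].to_numpy(), (10, 1))
        pom = PopulationOfModels(theta=np.zeros((10, 1)), biomarkers=Y)
        with pytest.raises(ValueError, match="degenerate"):
            divergence(pom, est, bins=32)


@pytest.fixture(scope="module")
def oracle_fixture():
    """12-candidate pool: 6 KDE draws + 6 shifted by +5 data SDs, with the
    exhaustive best subset (over all sizes 6..12) computed by enumeration."""
    data = synthetic.generate("sr", 30, seed=2)
    est = density.fit_density(data)
    rng = np.random.default_rng(0)
    pool_Y = np.vstack([
        sample_from_kde(est, 6, rng),
        sample_from_kde(est, 6, rng) + 5 * data.std(axis=0).to_numpy(),
    ])
    pool = PopulationOfModels(theta=np.arange(12, dtype=float)[:, None],
                              biomarkers=pool_Y, parameter_names=("id",))
    bins = 32
    Z = est.transform(pool.biomarkers)
    ws = refine._DivergenceWorkspace(Z, est, bins=bins)
    best_rho, best_set = np.inf, None
    for k in range(6, 13):
        for sub in itertools.combinations(range(12), k):
            mask = np.zeros(12, bool)
            mask[list(sub)] = True
            marg, pair = ws.sums_for(mask)
            _, r = ws.rho(marg, pair, k)
            if r < best_rho:
                best_rho, best_set = r, sub
    return data, est, pool, bins, best_rho, best_set


class TestAnnealRefine:
    def test_pool_at_min_size_returned_unchanged(self, sr_table, rng):
        est = density.fit_density(sr_table)
        Y = sample_from_kde(est, 20, rng)
        pool = PopulationOfModels(theta=np.zeros((20, 1)), biomarkers=Y)
        cfg = RefinementConfig(min_size=20, step_budget=100, bins=32)
        res = anneal_refine(pool, est, cfg, seed=0)
        assert res.pom.size == 20
        assert np.all(res.membership)

    def test_best_rho_trace_monotone_and_min_size_respected(self, sr_table,
                                                            rng):
        est = density.fit_density(sr_table)
        Y = sample_from_kde(est, 80, rng)
        pool = PopulationOfModels(theta=np.zeros((80, 1)), biomarkers=Y)
        cfg = RefinementConfig(min_size=40, step_budget=600, bins=32,
                               check_interval=200)
        res = anneal_refine(pool, est, cfg, seed=1)
        assert np.all(np.diff(res.trace[:, 2]) <= 1e-12)
        assert res.pom.size >= 40
        assert res.rho_best <= res.rho_initial + 1e-12

    def test_zero_temperature_limit_is_greedy(self, sr_table, rng):
        """With T -> 0 every accepted move lowers rho, so the current-rho
        trace (excluding restarts, which cannot occur) is non-increasing."""
        est = density.fit_density(sr_table)
        Y = sample_from_kde(est, 40, rng)
        pool = PopulationOfModels(theta=np.zeros((40, 1)), biomarkers=Y)
        cfg = RefinementConfig(T=1e-12, min_size=10, step_budget=400,
                               bins=32, check_interval=10 ** 9)
        res = anneal_refine(pool, est, cfg, seed=3)
        assert np.all(np.diff(res.trace[:, 1]) <= 1e-12)

    def test_incremental_sums_match_full_recomputation(self, sr_table, rng):
        """Toggling members incrementally reproduces the from-scratch kernel
        sums (and hence rho) to 1e-10."""
        est = density.fit_density(sr_table)
        Y = sample_from_kde(est, 50, rng)
        Z = est.transform(Y)
        ws = refine._DivergenceWorkspace(Z, est, bins=32)
        mask = np.ones(50, bool)
        marg, pair = ws.sums_for(mask)
        for m in rng.integers(0, 50, size=100):
            c_marg, c_pair = ws.member_contrib(int(m))
            sgn = -1.0 if mask[m] else 1.0
            if mask[m] and mask.sum() <= 2:
                continue
            marg = [marg[d] + sgn * c_marg[d] for d in range(7)]
            pair = {k: pair[k] + sgn * c_pair[k] for k in ws.pairs}
            mask[m] = not mask[m]
        marg_full, pair_full = ws.sums_for(mask)
        _, rho_inc = ws.rho(marg, pair, int(mask.sum()))
        _, rho_full = ws.rho(marg_full, pair_full, int(mask.sum()))
        assert rho_inc == pytest.approx(rho_full, abs=1e-10)

    def test_annealing_matches_exhaustive_oracle(self, oracle_fixture):
        """On the 12-candidate fixture the annealer recovers the brute-force
        best subset in >= 90% of 50 seeded runs."""
        data, est, pool, bins, best_rho, best_set = oracle_fixture
        hits = 0
        for seed in range(50):
            cfg = RefinementConfig(min_size=6, step_budget=800, bins=bins,
                                   check_interval=200)
            res = anneal_refine(pool, est, cfg, seed=seed)
            hits += tuple(np.flatnonzero(res.membership)) == best_set
        assert hits >= 45

    def test_seeded_reproducibility(self, sr_table, rng):
        est = density.fit_density(sr_table)
        Y = sample_from_kde(est, 40, rng)
        pool = PopulationOfModels(theta=np.zeros((40, 1)), biomarkers=Y)
        cfg = RefinementConfig(min_size=20, step_budget=300, bins=32)
        a = anneal_refine(pool, est, cfg, seed=9)
        b = anneal_refine(pool, est, cfg, seed=9)
        assert np.array_equal(a.membership, b.membership)
        assert a.rho_best == b.rho_best


class TestRefinementConfig:
    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            RefinementConfig(T=0.0)

    def test_invalid_min_size(self):
        with pytest.raises(ValueError):
            RefinementConfig(min_size=0)
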