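"""LD measures, solid-spine blocks, haplotype dosages and trend regression."""

from collections import Counter

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from coldgwas import haplotypes as hb
from coldgwas.core import HaplotypePanel, VariantMap
from coldgwas.simulate import SimulationConfig, simulate_population


def make_panel(haps):
    haps = np.asarray(haps, dtype=np.int8)
    m = haps.shape[1]
    variants = VariantMap(
        np.full(m, "1", dtype=object),
        np.arange(1, m + 1) * 1000,
        np.array([f"v{i}" for i in range(m)], dtype=object),
        np.stack([np.full(m, "A", dtype=object), np.full(m, "G", dtype=object)], axis=1),
    )
    return HaplotypePanel(haps, variants)


def dprime_counting_oracle(a, b):
    """2x2 gamete-count arithmetic, written independently."""
    n = len(a)
    c = Counter(zip(a.tolist(), b.tolist()))
    p11 = c[(1, 1)] / n
    pa = (c[(1, 0)] + c[(1, 1)]) / n
    pb = (c[(0, 1)] + c[(1, 1)]) / n
    D = p11 - pa * pb
    dmax = min(pa * (1 - pb), (1 - pa) * pb) if D >= 0 else min(pa * pb, (1 - pa) * (1 - pb))
    return abs(D) / dmax, D**2 / (pa * (1 - pa) * pb * (1 - pb))


class TestPairwiseLd:
    def test_perfect_ld_no_recombinants(self):
        a = np.array([1] * 5 + [0] * 5)
        dp, r2 = hb.pairwise_dprime_r2(a, a.copy())
        assert dp == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_exact_independence(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        dp, r2 = hb.pairwise_dprime_r2(a, b)
        assert dp == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_matches_counting_oracle_on_random_columns(self, rng):
        for _ in range(30):
            a = rng.integers(0, 2, size=50)
            b = rng.integers(0, 2, size=50)
            if a.min() == a.max() or b.min() == b.max():
                continue
            dp, r2 = hb.pairwise_dprime_r2(a, b)
            odp, or2 = dprime_counting_oracle(a, b)
            assert dp == pytest.approx(odp, abs=1e-12)
            assert r2 == pytest.approx(or2, abs=1e-12)

    def test_monomorphic_column_undefined(self):
        dp, r2 = hb.pairwise_dprime_r2(np.ones(10, dtype=int), np.array([0, 1] * 5))
        assert np.isnan(dp) and np.isnan(r2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hb.pairwise_dprime_r2(np.zeros(4, int), np.zeros(5, int))


def spine_oracle(panel, dprime_min=0.8):
    """Exhaustive search over all (start, end) pairs, then greedy leftmost.

    Monomorphic columns are excluded up front (undefined D'), matching the
    documented rule; indices are reported on the original panel.
    """
    poly = np.flatnonzero(
        (panel.haps == 0).any(axis=0) & (panel.haps == 1).any(axis=0)
    )
    H = panel.haps[:, poly]
    m = H.shape[1]

    def dp(i, j):
        return hb.pairwise_dprime_r2(H[:, i], H[:, j])[0]

    def valid(i, j):
        first = all((d := dp(i, k)) == d and d >= dprime_min for k in range(i + 1, j + 1))
        last = all((d := dp(k, j)) == d and d >= dprime_min for k in range(i, j))
        return first and last

    blocks = []
    i = 0
    while i < m - 1:
        best = -1
        for j in range(i + 1, m):
            if valid(i, j):
                best = j
        if best > i:
            blocks.append((int(poly[i]), int(poly[best])))
            i = best + 1
        else:
            i += 1
    return blocks


class TestSolidSpineBlocks:
    def test_perfect_ld_panel_is_single_block(self):
        haps = np.vstack([np.zeros((6, 10)), np.ones((6, 10))])
        blocks = hb.solid_spine_blocks(make_panel(haps))
        assert len(blocks) == 1
        assert blocks[0].n_snps == 10

    def test_ld_free_panel_has_little_block_coverage(self, rng):
        haps = rng.integers(0, 2, size=(400, 400))
        blocks = hb.solid_spine_blocks(make_panel(haps))
        covered = sum(b.n_snps for b in blocks)
        assert covered < 0.05 * 400

    def test_matches_exhaustive_oracle_on_ld_fixture(self):
        cfg = SimulationConfig(n_per_breed=30, m_snps=100, n_chrom=1, seed=21,
                               n_misplaced_low=0, n_misplaced_high=0)
        panel, *_ = simulate_population(cfg)
        blocks = hb.solid_spine_blocks(panel)
        got = [(b.snp_indices[0], b.snp_indices[-1]) for b in blocks]
        assert got == spine_oracle(panel)

    def test_emitted_blocks_satisfy_spine_invariant(self):
        cfg = SimulationConfig(n_per_breed=40, m_snps=200, n_chrom=2, seed=22,
                               n_misplaced_low=0, n_misplaced_high=0)
        panel, *_ = simulate_population(cfg)
        blocks = hb.solid_spine_blocks(panel)
        assert blocks, "fixture should contain LD blocks"
        for b in blocks:
            i, j = b.snp_indices[0], b.snp_indices[-1]
            for k in b.snp_indices[1:]:
                assert hb.pairwise_dprime_r2(panel.haps[:, i], panel.haps[:, k])[0] >= 0.8
            for k in b.snp_indices[:-1]:
                assert hb.pairwise_dprime_r2(panel.haps[:, k], panel.haps[:, j])[0] >= 0.8

    def test_unsorted_map_rejected(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(10, 5)))
        panel.variants.pos[:] = [5, 4, 3, 2, 1]
        with pytest.raises(ValueError, match="sorted"):
            hb.solid_spine_blocks(panel)


class TestBlockDosages:
    def test_two_class_block_rows_sum_to_two(self):
        haps = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [1, 1]])
        panel = make_panel(haps)
        block = hb.LDBlock("1", np.array([0, 1]), 1000, 2000)
        hdm = hb.block_haplotype_dosages(panel, block)
        assert hdm.dosages.shape == (3, 2)
        assert (hdm.dosages.sum(axis=1) == 2).all()

    def test_rare_haplotype_dropped(self, rng):
        # 200 chromosomes, one singleton class at frequency 0.005
        haps = np.tile([0, 0], (200, 1))
        haps[0] = [1, 1]
        panel = make_panel(haps)
        hdm = hb.block_haplotype_dosages(panel, hb.LDBlock("1", np.array([0, 1]), 1000, 2000))
        assert hdm.haplotypes == ["00"]
        assert hdm.n_dropped_rare == 1
        assert hdm.dosages[0, 0] == 1  # the carrier keeps one counted copy

    def test_counts_match_string_tabulation_oracle(self, rng):
        haps = rng.integers(0, 2, size=(60, 4))
        panel = make_panel(haps)
        hdm = hb.block_haplotype_dosages(
            panel, hb.LDBlock("1", np.arange(4), 1000, 4000), freq_min=0.0
        )
        oracle = Counter("".join(map(str, row)) for row in haps)
        got = dict(zip(hdm.haplotypes, np.asarray(hdm.frequencies) * 60))
        assert {h: round(c) for h, c in got.items()} == dict(oracle)
        assert (hdm.dosages.sum(axis=1) == 2).all()


class TestAdjustPhenotype:
    def test_exact_covariate_phenotype_gives_zero_residuals(self, rng):
        sex = rng.integers(1, 3, 30)
        breed = rng.integers(1, 3, 30)
        resid = hb.adjust_phenotype(2.0 * sex, sex, breed)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_orthogonal_phenotype_just_centered(self):
        sex = np.array([1, 1, 2, 2])
        breed = np.array([1, 2, 1, 2])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to both contrasts
        np.testing.assert_allclose(hb.adjust_phenotype(y, sex, breed), y - y.mean(), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=6)
        sex = np.array([1, 2, 1, 2, 1, 2])
        breed = np.array([1, 1, 2, 2, 1, 2])
        X = np.column_stack([np.ones(6), sex, breed])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(hb.adjust_phenotype(y, sex, breed), y - X @ beta, atol=1e-10)

    def test_constant_phenotype_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out = hb.adjust_phenotype(np.ones(10), np.ones(10), np.ones(10))
        assert (out == 0).all()


class TestHtrTest:
    def test_two_haplotype_block_equals_dosage_regression(self, rng):
        n = 80
        d = rng.integers(0, 3, size=n)
        hdm = hb.HaplotypeDosageMatrix(
            np.column_stack([2 - d, d]).astype(np.int8), ["00", "11"],
            np.array([0.6, 0.4]), 0,
        )
        y = 0.3 * d + rng.normal(size=n)
        y = y - y.mean()
        F, df1, df2, p = hb.htr_test(y, hdm)
        ols = sm.OLS(y, sm.add_constant(d.astype(float))).fit()
        assert df1 == 1 and df2 == n - 2
        assert p == pytest.approx(ols.f_pvalue, rel=1e-8)

    def test_orthogonal_dosages_give_null_f(self, rng):
        n = 60
        d = np.resize([0, 1, 2], n).astype(np.int8)
        hdm = hb.HaplotypeDosageMatrix(
            np.column_stack([2 - d, d]), ["00", "11"], np.array([0.6, 0.4]), 0
        )
        y = np.resize([1.0, 1.0, 1.0, -1.0, -1.0, -1.0], n)
        y = y - y.mean()
        y -= (y @ d) / (d @ d) * d  # force exact orthogonality
        F, _, _, p = hb.htr_test(y, hdm)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_block_skipped_when_underdetermined(self):
        hdm = hb.HaplotypeDosageMatrix(
            np.eye(3, dtype=np.int8), ["a", "b", "c"], np.full(3, 1 / 3), 0
        )
        with pytest.raises(ValueError, match="not testable"):
            hb.htr_test(np.array([1.0, 2.0, 0.5]), hdm)

    def test_permuted_phenotype_p_uniform(self, rng):
        cfg = SimulationConfig(n_per_breed=40, m_snps=60, n_chrom=1, seed=31,
                               n_misplaced_low=0, n_misplaced_high=0)
        panel, table, samples, _ = simulate_population(cfg)
        blocks = hb.solid_spine_blocks(panel)
        assert blocks
        hdm = hb.block_haplotype_dosages(panel, blocks[0])
        y = rng.normal(size=table.n_samples)
        ps = []
        for _ in range(300):
            ps.append(hb.htr_test(rng.permutation(y), hdm)[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGenomicControl:
    def test_identity_at_unit_inflation(self):
        p = np.linspace(0.005, 0.995, 199)  # median exactly 0.5 -> lambda = 1
        lam, adj = hb.genomic_control(p)
        assert lam == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(adj, p, atol=1e-12)

    def test_uniform_p_nearly_unchanged(self, rng):
        p = rng.uniform(size=5000)
        lam, adj = hb.genomic_control(p)
        assert lam == pytest.approx(1.0, abs=0.05)
        assert np.abs(adj - p).max() < 0.05

    def test_constructed_double_inflation_recovered(self):
        p0 = (np.arange(1, 1000) - 0.5) / 999  # symmetric grid: median chi2 exact
        chi0 = stats.chi2.isf(p0, 1)
        p_infl = stats.chi2.sf(2 * chi0, 1)
        lam, adj = hb.genomic_control(p_infl)
        assert lam == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(adj, p0, atol=1e-6)
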