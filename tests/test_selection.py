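"""Sweep statistics (H1/H12, pi, Tajima's D), DCMS combination, calibration."""

import numpy as np
import pytest
from scipy import stats

from coldgwas import selection as sel
from coldgwas.simulate import SimulationConfig, SweepConfig, plant_sweep, simulate_population
from test_haplotypes import make_panel


class TestHaplotypeHomozygosity:
    @pytest.mark.parametrize(
        "freqs, h1, h12",
        [
            ([1.0], 1.0, 1.0),
            ([0.5, 0.5], 0.5, 1.0),
            ([0.4, 0.3, 0.2, 0.1], 0.30, 0.54),
        ],
    )
    def test_closed_form_values(self, freqs, h1, h12):
        got = sel.haplotype_homozygosity(freqs)
        assert got == (pytest.approx(h1), pytest.approx(h12))

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            sel.haplotype_homozygosity([])

    def test_h12_dominates_h1(self, rng):
        for _ in range(50):
            f = rng.dirichlet(np.ones(rng.integers(2, 12)))
            h1, h12 = sel.haplotype_homozygosity(f)
            assert 0 < h1 <= h12 <= 1


class TestNucleotideDiversity:
    def test_identical_haplotypes_zero(self):
        assert sel.nucleotide_diversity(np.zeros((5, 8), int)) == 0.0

    def test_four_haplotypes_two_sites(self):
        # {AA, AA, AT, AT}: 4 differing pairs of 6, over 2 sites -> 1/3
        H = np.array([[0, 0], [0, 0], [0, 1], [0, 1]])
        assert sel.nucleotide_diversity(H) == pytest.approx(1 / 3)

    def test_matches_all_pairs_oracle(self, rng):
        H = rng.integers(0, 2, size=(20, 15))
        n = len(H)
        total = sum(
            (H[i] != H[j]).sum() for i in range(n) for j in range(i + 1, n)
        )
        oracle = total / (n * (n - 1) / 2) / H.shape[1]
        assert sel.nucleotide_diversity(H) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_row_order_and_allele_swap(self, rng):
        H = rng.integers(0, 2, size=(12, 9))
        base = sel.nucleotide_diversity(H)
        assert sel.nucleotide_diversity(H[rng.permutation(12)]) == pytest.approx(base)
        assert sel.nucleotide_diversity(1 - H) == pytest.approx(base)


def tajima_oracle(H):
    """Independent evaluation of the 1989 formulas."""
    n, _ = H.shape
    c = H.sum(axis=0)
    S = int(((c > 0) & (c < n)).sum())
    if S == 0:
        return np.nan
    pi = sum(
        (H[i] != H[j]).sum() for i in range(n) for j in range(i + 1, n)
    ) / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(sel.tajimas_d(np.zeros((6, 5), int)))

    def test_constants_via_small_n_harmonic_number(self):
        # at n = 4 the Watterson correction is 1 + 1/2 + 1/3
        H = np.array([[1, 0], [0, 0], [0, 0], [0, 0]])
        d = sel.tajimas_d(H)
        assert d == pytest.approx(tajima_oracle(H), abs=1e-12)

    def test_matches_formula_oracle_on_random_panels(self, rng):
        for _ in range(20):
            H = rng.integers(0, 2, size=(rng.integers(4, 30), rng.integers(3, 25)))
            got, want = sel.tajimas_d(H), tajima_oracle(H)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_sweep_lowers_d(self):
        """Planted hard sweeps push Tajima's D down relative to neutral SNPs."""
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_per_breed=50, m_snps=1000, n_chrom=1, seed=seed,
                                   n_misplaced_low=0, n_misplaced_high=0)
            panel, *_ = simulate_population(cfg)
            pos = panel.variants.pos
            lo, hi = pos[400], pos[600]
            swept = plant_sweep(panel, "1", lo, hi, 0.9, seed=seed)
            track = sel.windowed_tracks(swept)
            in_sweep = (pos >= lo) & (pos <= hi)
            d = track["tajd"].to_numpy()
            if np.nanmedian(d[in_sweep]) < np.nanmedian(d[~in_sweep]):
                hits += 1
        assert hits >= 9


class TestWindowedTracks:
    def test_degenerate_constant_panel(self):
        panel = make_panel(np.zeros((10, 20), int))
        panel.haps[:, 0] = [1] * 5 + [0] * 5  # keep one polymorphic site
        track = sel.windowed_tracks(panel, window_size=5)
        inner = track.iloc[5:-2]  # windows clear of the polymorphic site, untruncated
        assert (inner["H1"] == 1).all()
        assert (inner["pi"] == 0).all()
        assert inner["tajd"].isna().all()

    def test_rank_of_max_is_n_over_n_plus_1(self):
        cfg = SimulationConfig(n_per_breed=30, m_snps=400, n_chrom=1, seed=13,
                               n_misplaced_low=0, n_misplaced_high=0)
        panel, *_ = simulate_population(cfg)
        track = sel.windowed_tracks(panel)
        h12 = track["H12"].to_numpy()
        finite = np.isfinite(h12)
        top = np.nanargmax(h12)
        n_unique_max = (h12[finite] == h12[top]).sum()
        if n_unique_max == 1:
            assert track["rank_H12"][top] == pytest.approx(finite.sum() / (finite.sum() + 1))
        # sweep-direction p of the max is the smallest
        assert track["p_H12"][top] == np.nanmin(track["p_H12"])

    def test_windows_truncated_below_minimum_are_missing(self, rng):
        # a 4-SNP chromosome can never reach the 5-SNP minimum window
        panel = make_panel(rng.integers(0, 2, size=(12, 4)))
        track = sel.windowed_tracks(panel, window_size=31, min_window=5)
        assert track["H1"].isna().all()
        # while an 8-SNP chromosome keeps its interior
        panel8 = make_panel(rng.integers(0, 2, size=(12, 8)))
        track8 = sel.windowed_tracks(panel8, window_size=9, min_window=7)
        assert track8["H1"].notna().sum() == 8 - 2 * 2  # two truncated at each edge


class TestDcmsCombine:
    def test_single_statistic_log_odds(self):
        p = np.array([[0.5], [0.1], [0.9]])
        v = np.array([[1.0], [2.0], [3.0]])
        scores, w = sel.dcms_combine(p, v)
        assert w[0] == pytest.approx(1.0)
        np.testing.assert_allclose(scores, np.log((1 - p[:, 0]) / p[:, 0]))
        assert scores[0] == pytest.approx(0.0)

    def test_duplicated_statistic_invariance(self, rng):
        p1 = rng.uniform(0.01, 0.99, size=200)
        v1 = rng.normal(size=200)
        single, _ = sel.dcms_combine(p1[:, None], v1[:, None])
        doubled, w = sel.dcms_combine(
            np.column_stack([p1, p1]), np.column_stack([v1, v1])
        )
        np.testing.assert_allclose(w, [2.0, 2.0])
        np.testing.assert_allclose(doubled, single, atol=1e-12)

    def test_monotone_decreasing_in_each_p(self, rng):
        p = rng.uniform(0.1, 0.9, size=(50, 3))
        v = rng.normal(size=(50, 3))
        base, _ = sel.dcms_combine(p, v)
        p2 = p.copy()
        p2[7, 1] *= 0.5
        bumped, _ = sel.dcms_combine(p2, v)
        assert bumped[7] > base[7]
        np.testing.assert_allclose(np.delete(bumped, 7), np.delete(base, 7))

    def test_zero_variance_statistic_excluded(self, rng):
        p = rng.uniform(0.1, 0.9, size=(150, 2))
        v = np.column_stack([rng.normal(size=150), np.ones(150)])
        with pytest.warns(UserWarning, match="zero variance"):
            scores, w = sel.dcms_combine(p, v)
        single, _ = sel.dcms_combine(p[:, :1], v[:, :1])
        np.testing.assert_allclose(scores, single)


class TestRobustNormalPvalues:
    def test_standard_normal_self_consistency(self, rng):
        x = rng.normal(size=100_000)
        p, loc, scale = sel.robust_normal_pvalues(x)
        assert loc == pytest.approx(0.0, abs=0.02)
        assert scale == pytest.approx(1.0, abs=0.02)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_huber_location_resists_contamination(self, rng):
        clean = rng.normal(size=9_500)
        x = np.concatenate([clean, rng.normal(12, 1, size=500)])
        _, loc, _ = sel.robust_normal_pvalues(x)
        mean_shift = x.mean() - clean.mean()
        huber_shift = loc - clean.mean()
        assert huber_shift < 0.2 * mean_shift

    def test_score_at_location_has_p_half(self, rng):
        x = rng.normal(size=1000)
        p, loc, scale = sel.robust_normal_pvalues(np.append(x, loc := 0.0))
        # recompute with the fitted location appended exactly
        p2, loc2, scale2 = sel.robust_normal_pvalues(np.append(x, np.median(x)))
        assert 0.3 < p2[-1] < 0.7


class TestQvalues:
    def test_uniform_null_close_to_bh(self, rng):
        p = rng.uniform(size=5000)
        q = sel.qvalues(p)
        bh = sel.qvalues(p, method="bh")
        assert np.abs(q - bh).max() < 0.15
        assert np.nanmin(q / np.maximum(bh, 1e-300)) > 0.7

    def test_bh_method_is_exactly_bh(self, rng):
        from coldgwas.gwas import bh_fdr

        p = rng.uniform(size=300)
        np.testing.assert_allclose(sel.qvalues(p, method="bh"), bh_fdr(p))

    def test_matches_independent_storey_implementation(self, rng):
        p = np.concatenate([rng.uniform(size=800), rng.beta(0.2, 5, size=200)])
        q = sel.qvalues(p)

        lam = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > l).mean() / (1 - l) for l in lam])
        pi0 = min(max(float(np.polyval(np.polyfit(lam, pi0_l, 3), 0.95)), 1e-8), 1.0)
        m = len(p)
        order = np.argsort(p)
        qo = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, pi0 * p[i] * m / rank)
            qo[i] = prev
        np.testing.assert_allclose(q, qo, atol=1e-6)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            sel.qvalues(np.array([0.0, 0.5]))
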