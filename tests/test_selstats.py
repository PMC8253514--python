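"""Statistic correctness: hand-worked values and brute-force oracles.

The oracles here recompute each statistic from first principles
(explicit pairwise loops, exact haplotype counting with a Counter,
variance-component ANOVA for FST) and must agree with the vectorized
implementations to 1e-9.
"""

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import make_variant_table
from sweepscan.popsim import SimConfig, simulate_population
from sweepscan.selstats import (
    WindowSpec,
    build_stat_panel,
    garud_h,
    running_median,
    site_pi,
    sliding_windows,
    tajimas_d,
    wc_fst,
)
from tests.conftest import tiny_config

# ---------------------------------------------------------------- oracles


def garud_oracle(window):
    counts = sorted(Counter(tuple(r) for r in window).values(), reverse=True)
    n = sum(counts)
    p = [c / n for c in counts]
    h1 = sum(x * x for x in p)
    h12 = (p[0] + (p[1] if len(p) > 1 else 0.0)) ** 2 + sum(x * x for x in p[2:])
    h2 = h1 - p[0] ** 2
    return h1, h12, (0.0 if h2 == 0 else h2 / h1)


def pi_oracle(column):
    """Mean pairwise difference at one site by explicit enumeration."""
    n = len(column)
    diffs = sum(1 for a, b in combinations(column, 2) if a != b)
    return diffs / (n * (n - 1) / 2)


def tajima_oracle(window_haps):
    """Tajima's D from explicit pairwise differences and textbook constants."""
    n = window_haps.shape[0]
    s = sum(1 for col in window_haps.T if 0 < col.sum() < n)
    if s == 0:
        return np.nan
    pairs = list(combinations(range(n), 2))
    pi = sum(np.sum(window_haps[i] != window_haps[j]) for i, j in pairs) / len(pairs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * s + (c2 / (a1 * a1 + a2)) * s * (s - 1)
    return (pi - s / a1) / np.sqrt(var)


def wc_fst_anova_oracle(dos1, dos2):
    """Two-population Weir-Cockerham theta via the ANOVA mean squares
    (between-population, between-individual, within-individual), an
    algebraically independent arrangement of the estimator."""
    out = []
    for j in range(dos1.shape[1]):
        g1 = dos1[:, j][dos1[:, j] >= 0]
        g2 = dos2[:, j][dos2[:, j] >= 0]
        if len(g1) < 2 or len(g2) < 2:
            out.append(np.nan)
            continue
        p1, p2 = g1.mean() / 2, g2.mean() / 2
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            out.append(np.nan)
            continue
        n1, n2 = len(g1), len(g2)
        ntot = n1 + n2
        pbar_w = (n1 * p1 + n2 * p2) / ntot
        ssg = 0.5 * (np.sum(g1 == 1) + np.sum(g2 == 1))
        msg = ssg / ntot
        ssi = sum(2 * (g / 2 - p) ** 2 for g, p in [(x, p1) for x in g1] + [(x, p2) for x in g2])
        msi = ssi / (ntot - 2)
        ssp = 2 * n1 * (p1 - pbar_w) ** 2 + 2 * n2 * (p2 - pbar_w) ** 2
        msp = ssp / 1.0
        nc = (ntot - (n1 * n1 + n2 * n2) / ntot) / 1.0
        a = (msp - msi) / (2 * nc)
        b = (msi - msg) / 2.0
        c = msg
        denom = a + b + c
        out.append(a / denom if denom != 0 else np.nan)
    return np.array(out)


# ---------------------------------------------------- hand-worked examples


class TestGarudH:
    def test_single_haplotype_class(self):
        win = np.zeros((10, 25), dtype=np.int8)
        assert garud_h(win) == (1.0, 1.0, 0.0)

    def test_spectrum_half_quarter_quarter(self):
        # frequencies (0.5, 0.25, 0.25): H1 = .375, H12 = .625, H2/H1 = 1/3
        win = np.array([[0, 0]] * 4 + [[0, 1]] * 2 + [[1, 1]] * 2, dtype=np.int8)
        h1, h12, h2h1 = garud_h(win)
        assert h1 == pytest.approx(0.375)
        assert h12 == pytest.approx(0.625)
        assert h2h1 == pytest.approx(1.0 / 3.0)

    def test_all_distinct_uniform_spectrum(self):
        n = 8  # 2N distinct haplotypes -> closed form
        win = np.eye(n, dtype=np.int8)
        h1, h12, _ = garud_h(win)
        assert h1 == pytest.approx(1.0 / n)
        assert h12 == pytest.approx(4.0 / n**2 + (n - 2) / n**2)

    def test_missing_allele_rejected(self):
        win = np.zeros((4, 5), dtype=np.int8)
        win[0, 0] = -1
        with pytest.raises(ValueError, match="phased"):
            garud_h(win)


class TestTajimasD:
    # 000/001/011/111: pi = 10/6, theta_W = 3/a1, D ~ +0.17
    HAPS = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int8)

    def test_hand_worked_n4(self):
        alt = self.HAPS.sum(axis=0)
        d = tajimas_d(alt, np.full(3, 4))
        assert d == pytest.approx(tajima_oracle(self.HAPS), abs=1e-12)
        assert d == pytest.approx(0.1677, abs=5e-4)

    def test_duplicated_haplotypes_preserve_sign(self):
        doubled = np.repeat(self.HAPS, 2, axis=0)
        alt = doubled.sum(axis=0)
        d8 = tajimas_d(alt, np.full(3, 8))
        assert d8 == pytest.approx(tajima_oracle(doubled), abs=1e-12)
        assert d8 > 0

    def test_no_segregating_sites_is_missing(self):
        assert np.isnan(tajimas_d(np.array([0, 4]), np.array([4, 4])))

    def test_small_n_is_missing(self):
        with pytest.warns(UserWarning, match="n="):
            assert np.isnan(tajimas_d(np.array([1]), np.array([3])))


class TestSitePi:
    def test_monomorphic_zero(self):
        assert site_pi(np.array([0]), np.array([10]))[0] == 0.0

    def test_hand_worked(self):
        # n=10, 4 alt: 2*4*6/90
        assert site_pi(np.array([4]), np.array([10]))[0] == pytest.approx(48 / 90)

    def test_single_pair(self):
        assert site_pi(np.array([1]), np.array([2]))[0] == 1.0

    def test_n_below_two_missing(self):
        assert np.isnan(site_pi(np.array([1]), np.array([1]))[0])


class TestWcFst:
    def test_fixed_difference(self):
        d1 = np.full((5, 1), 2, dtype=np.int8)
        d2 = np.zeros((5, 1), dtype=np.int8)
        assert wc_fst(d1, d2)[0] == pytest.approx(1.0)

    def test_all_heterozygotes_truncates_to_zero(self):
        d = np.ones((5, 1), dtype=np.int8)
        assert wc_fst(d, d.copy())[0] == 0.0

    def test_three_genotype_hand_case(self):
        # pop1 {3 AA, 2 Aa}; pop2 {1 AA, 2 Aa, 2 aa} -> a=.055 b=.025 c=.2
        d1 = np.array([[2], [2], [2], [1], [1]], dtype=np.int8)
        d2 = np.array([[2], [1], [1], [0], [0]], dtype=np.int8)
        theta = wc_fst(d1, d2)[0]
        assert theta == pytest.approx(0.055 / 0.28, abs=1e-12)
        assert theta == pytest.approx(wc_fst_anova_oracle(d1, d2)[0], abs=1e-12)

    def test_monomorphic_missing(self):
        d = np.zeros((4, 1), dtype=np.int8)
        assert np.isnan(wc_fst(d, d.copy())[0])


class TestRunningMedian:
    def test_constant_identity(self):
        x = np.full(40, 3.5)
        assert np.array_equal(running_median(x, 31), x)

    def test_hand_worked_shrinking_ends(self):
        out = running_median(np.array([1.0, 9, 2, 8, 3]), 3)
        assert np.array_equal(out, [1, 2, 8, 3, 3])

    def test_outlier_removed_in_interior(self):
        x = np.full(100, 1.0)
        x[50] = 99.0
        assert running_median(x, 31)[50] == 1.0

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            running_median(np.arange(5.0), 4)

    def test_missing_excluded(self):
        x = np.array([1.0, np.nan, 3.0, np.nan, np.nan])
        out = running_median(x, 3)
        assert out[1] == 2.0  # median of {1,3}
        assert np.isnan(out[4])  # window all-missing/edge shrink to the NaN


# ------------------------------------------------------------- windows


class TestSlidingWindows:
    def _variants(self, n, chrom="1"):
        return make_variant_table([chrom] * n, np.arange(1, n + 1) * 100)

    def test_exact_window_count(self):
        spec = WindowSpec()
        assert len(sliding_windows(self._variants(25), spec)) == 1
        assert len(sliding_windows(self._variants(27), spec)) == 3

    def test_too_few_snps_warns(self):
        with pytest.warns(UserWarning, match="no windows"):
            w = sliding_windows(self._variants(24), WindowSpec())
        assert len(w) == 0

    def test_anchor_is_central_snp(self):
        w = sliding_windows(self._variants(25), WindowSpec())
        assert w.anchor_snp.iloc[0] == "1:1300"  # 13th of 25

    def test_windows_do_not_span_chromosomes(self):
        v = pd.concat(
            [self._variants(30, "1"), self._variants(30, "2")], ignore_index=True
        )
        w = sliding_windows(v, WindowSpec())
        assert len(w) == 2 * (30 - 25 + 1)
        assert set(w.chrom) == {"1", "2"}


class TestBuildStatPanel:
    def test_join_by_snp_id_and_missing_propagation(self):
        a = pd.DataFrame(
            {"snp_id": ["s1", "s2", "s3"], "chrom": "1", "pos": [10, 20, 30], "x": [1.0, 2, 3]}
        )
        b = pd.DataFrame({"snp_id": ["s2", "s3"], "y": [5.0, 6]})
        panel = build_stat_panel({"x": a, "y": b})
        assert len(panel) == 3
        assert np.isnan(panel.loc[panel.snp_id == "s1", "y"]).all()

    def test_duplicate_snp_id_rejected(self):
        a = pd.DataFrame({"snp_id": ["s1", "s1"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicated"):
            build_stat_panel({"x": a})

    def test_order_independence(self):
        a = pd.DataFrame(
            {"snp_id": ["s1", "s2"], "chrom": "1", "pos": [10, 20], "x": [1.0, 2]}
        )
        b = pd.DataFrame({"snp_id": ["s2", "s1"], "y": [5.0, 6]})
        p1 = build_stat_panel({"x": a, "y": b})
        p2 = build_stat_panel({"x": a, "y": b.iloc[::-1].reset_index(drop=True)})
        pd.testing.assert_frame_equal(p1, p2)


# ------------------------------------------- oracle equivalence at scale


def _simulated_haplotypes(seed):
    hap, _ = simulate_population(tiny_config(seed=seed))
    return hap


@pytest.mark.parametrize("seed", range(10))
def test_statistics_match_bruteforce_oracles(seed):
    """Vectorized statistics equal first-principles oracles to 1e-9 on
    simulated data (windows of the focal half of the sample)."""
    hap = _simulated_haplotypes(seed)
    rng = np.random.default_rng(seed)
    sub = hap.haplotypes[:20]  # focal group: first 10 diploids
    rest = hap.haplotypes[20:]
    m = sub.shape[1]
    if m < 30:
        pytest.skip("degenerate tiny simulation")
    # windows of 25 sites at random starts
    for start in rng.choice(m - 25, size=5, replace=False):
        win = sub[:, start : start + 25]
        got = garud_h(win)
        want = garud_oracle(win)
        assert got == pytest.approx(want, abs=1e-9)
        alt = win.sum(axis=0)
        d = tajimas_d(alt, np.full(25, win.shape[0]))
        want_d = tajima_oracle(win)
        if np.isnan(want_d):
            assert np.isnan(d)
        else:
            assert d == pytest.approx(want_d, abs=1e-9)
    # per-site pi on a random site subset
    cols = rng.choice(m, size=20, replace=False)
    pi = site_pi(sub[:, cols].sum(axis=0), np.full(20, sub.shape[0]))
    for k, j in enumerate(cols):
        assert pi[k] == pytest.approx(pi_oracle(sub[:, j]), abs=1e-9)
    # FST pre-truncation vs ANOVA oracle
    d1 = (sub[0::2] + sub[1::2]).astype(np.int8)
    d2 = (rest[0::2] + rest[1::2]).astype(np.int8)
    theta = wc_fst(d1[:, cols], d2[:, cols], truncate=False)
    want = wc_fst_anova_oracle(d1[:, cols], d2[:, cols])
    both = ~(np.isnan(theta) | np.isnan(want))
    assert np.isnan(theta).tolist() == np.isnan(want).tolist()
    np.testing.assert_allclose(theta[both], want[both], atol=1e-9)


def test_sample_order_permutation_invariance():
    hap = _simulated_haplotypes(3)
    sub = hap.haplotypes[:20, :25]
    rng = np.random.default_rng(0)
    perm = rng.permutation(20)
    assert garud_h(sub) == pytest.approx(garud_h(sub[perm]), abs=1e-12)


def test_h12_bounds_invariants():
    for seed in range(5):
        hap = _simulated_haplotypes(seed)
        sub = hap.haplotypes[:20]
        if sub.shape[1] < 25:
            continue
        h1, h12, h2h1 = garud_h(sub[:, :25])
        assert h12 >= h1 - 1e-12
        assert 0 <= h2h1 < 1
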