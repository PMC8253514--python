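"""Per-SNP and per-window selection/diversity statistics.

Five statistics feed the composite scan:

* Garud's H12 and H2/H1 — haplotype-homozygosity spectra in sliding
  windows of 25 SNPs (step 1), separating hard from soft sweeps.
* Tajima's D over the same 25-SNP windows.
* Per-site nucleotide diversity pi, smoothed with a 31-SNP running median.
* Weir-Cockerham FST (focal group vs pooled remainder), negative values
  truncated to zero, smoothed with a 31-SNP running median.

Window statistics are anchored to the central SNP of each window so all
five can be joined by SNP id into one panel.  Statistics that cannot be
computed (incomplete windows near chromosome ends, monomorphic
contrasts) are NaN, never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan.containers import GenotypeMatrix, HaplotypeMatrix

STAT_COLUMNS = ["h2h1", "h12", "tajimas_d", "pi_smoothed", "fst_smoothed"]


@dataclass
class WindowSpec:
    """Sliding-window layout for haplotype and Tajima's D statistics."""

    window_snps: int = 25
    step_snps: int = 1
    smooth_snps: int = 31  # running-median width for pi and FST

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.step_snps < 1:
            raise ValueError("step_snps must be >= 1")
        if self.smooth_snps % 2 == 0:
            raise ValueError("smooth_snps must be odd")

    @property
    def anchor_offset(self) -> int:
        """Index of the window's representative (central) SNP."""
        return (self.window_snps - 1) // 2


def sliding_windows(variants: pd.DataFrame, spec: WindowSpec) -> pd.DataFrame:
    """Enumerate windows per chromosome.

    Returns one row per window: chrom, start/stop column index into the
    variant table, first/last bp, and the anchor SNP id.  Chromosomes
    with fewer than ``window_snps`` SNPs yield no windows (with a
    warning); windows never span chromosomes.
    """
    rows = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        m = len(idx)
        if m < spec.window_snps:
            warnings.warn(
                f"chromosome {chrom}: {m} SNPs < window of {spec.window_snps}; no windows"
            )
            continue
        for s in range(0, m - spec.window_snps + 1, spec.step_snps):
            lo, hi = idx[s], idx[s + spec.window_snps - 1]
            anchor = idx[s + spec.anchor_offset]
            rows.append(
                (
                    chrom,
                    lo,
                    hi,
                    int(variants.at[lo, "pos"]),
                    int(variants.at[hi, "pos"]),
                    variants.at[anchor, "snp_id"],
                    anchor,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_idx",
            "stop_idx",
            "first_bp",
            "last_bp",
            "anchor_snp",
            "anchor_idx",
        ],
    )


def garud_h(window_haps: np.ndarray) -> tuple[float, float, float]:
    """Garud's (H1, H12, H2/H1) from exact haplotype string counts.

    ``window_haps`` is 2N x w phased 0/1 alleles with no missing calls.
    H1 = sum p_i^2; H12 = (p1+p2)^2 + sum_{i>=3} p_i^2; H2 = H1 - p1^2.
    H2/H1 is 0 when a single haplotype class is present.
    """
    arr = np.asarray(window_haps)
    if arr.ndim != 2:
        raise ValueError("window haplotypes must be 2-D")
    if ((arr != 0) & (arr != 1)).any():
        raise ValueError(
            "haplotype window contains missing or non-binary alleles; "
            "haplotype statistics require phased, complete input"
        )
    # pack each row's alleles into an integer key for exact counting
    key = arr.astype(np.uint64) @ (np.uint64(1) << np.arange(arr.shape[1], dtype=np.uint64))
    _, counts = np.unique(key, return_counts=True)
    p = np.sort(counts / arr.shape[0])[::-1]
    h1 = float(np.sum(p**2))
    h12 = float((p[0] + (p[1] if len(p) > 1 else 0.0)) ** 2 + np.sum(p[2:] ** 2))
    h2 = h1 - float(p[0] ** 2)
    h2h1 = 0.0 if h2 == 0.0 else h2 / h1
    return h1, h12, h2h1


def _spectrum_stats(counts: np.ndarray, n: int) -> tuple[float, float, float]:
    """(H1, H12, H2/H1) from a haplotype-class count vector."""
    p = np.sort(counts / n)[::-1]
    h1 = float(np.sum(p**2))
    h12 = float((p[0] + (p[1] if len(p) > 1 else 0.0)) ** 2 + np.sum(p[2:] ** 2))
    h2 = h1 - float(p[0] ** 2)
    return h1, h12, (0.0 if h2 == 0.0 else h2 / h1)


def _garud_windows(
    hap: np.ndarray, starts: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Garud statistics for many fixed-width windows at once.

    Haplotype strings are packed into exact integer keys (w <= 52 fits a
    float64 mantissa); the per-window spectrum comes from key counts.
    """
    n_hap = hap.shape[0]
    n_win = len(starts)
    h1s = np.empty(n_win)
    h12s = np.empty(n_win)
    h2h1s = np.empty(n_win)
    if n_win == 0:
        return h1s, h12s, h2h1s
    if w > 52:  # cannot pack exactly; fall back to the single-window path
        for i, s in enumerate(starts):
            h1s[i], h12s[i], h2h1s[i] = garud_h(hap[:, s : s + w])
        return h1s, h12s, h2h1s
    view = np.lib.stride_tricks.sliding_window_view(hap, w, axis=1)
    powers = 2.0 ** np.arange(w)
    keys = view[:, starts, :].astype(np.float64) @ powers  # (n_hap, n_win)
    keys = np.sort(keys, axis=0)
    for i in range(n_win):
        col = keys[:, i]
        boundaries = np.nonzero(np.diff(col))[0]
        edges = np.concatenate([[0], boundaries + 1, [n_hap]])
        counts = np.diff(edges)
        h1s[i], h12s[i], h2h1s[i] = _spectrum_stats(counts, n_hap)
    return h1s, h12s, h2h1s


def _tajima_windows(
    alt: np.ndarray, called: np.ndarray, starts: np.ndarray, w: int
) -> np.ndarray:
    """Tajima's D for many fixed-width windows via sliding sums."""
    starts = np.asarray(starts)
    seg = ((alt > 0) & (alt < called)).astype(float)
    cs_seg = np.concatenate([[0.0], np.cumsum(seg)])
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = 2.0 * alt * (called - alt) / (called * (called - 1.0))
    cs_pi = np.concatenate([[0.0], np.cumsum(pi_site)])
    s_win = cs_seg[starts + w] - cs_seg[starts]
    pi_win = cs_pi[starts + w] - cs_pi[starts]
    n_view = np.lib.stride_tricks.sliding_window_view(called, w)
    n_min = n_view[starts].min(axis=1).astype(int)
    out = np.full(len(starts), np.nan)
    for n in np.unique(n_min):
        if n < 4:
            continue
        sel = n_min == n
        s = s_win[sel]
        a1 = np.sum(1.0 / np.arange(1, n))
        e1, e2 = _tajima_constants(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (pi_win[sel] - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1.0))
        d[s == 0] = np.nan
        out[sel] = d
    return out


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) variance constants for n chromosomes (standard a1..c2)."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(alt_counts: np.ndarray, called_counts: np.ndarray) -> float:
    """Tajima's D for one window of sites.

    ``alt_counts``/``called_counts`` give per-site alternate-allele and
    called-chromosome counts.  A single n — the minimum called count
    across the window's sites — is used for the constants (conservative
    with mixed call rates).  Returns NaN when no site segregates or
    n < 4.
    """
    alt = np.asarray(alt_counts, dtype=float)
    called = np.asarray(called_counts, dtype=float)
    n = int(called.min()) if len(called) else 0
    if n < 4:
        if n > 0:
            warnings.warn(f"Tajima's D undefined for n={n} < 4 chromosomes")
        return np.nan
    seg = (alt > 0) & (alt < called)
    s = int(seg.sum())
    if s == 0:
        return np.nan
    pi = float(np.sum(2.0 * alt * (called - alt) / (called * (called - 1.0))))
    a1 = np.sum(1.0 / np.arange(1, n))
    theta_w = s / a1
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return (pi - theta_w) / np.sqrt(var)


def site_pi(alt_count: np.ndarray, called_count: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2*na*nr/(n*(n-1)); NaN when n < 2."""
    alt = np.asarray(alt_count, dtype=float)
    n = np.asarray(called_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def wc_fst(
    dosages_focal: np.ndarray, dosages_rest: np.ndarray, truncate: bool = True
) -> np.ndarray:
    """Weir-Cockerham (1984) two-population theta per SNP.

    Inputs are diploid dosage matrices (samples x SNPs, -1 = missing)
    for the focal group and the pooled remainder.  Negative estimates
    (or non-positive denominators) are truncated to 0 when ``truncate``.
    SNPs monomorphic across both groups, or with fewer than 2 called
    diploids on either side, are NaN.
    """
    out = np.full(dosages_focal.shape[1], np.nan)
    stats = []
    for d in (dosages_focal, dosages_rest):
        d = np.asarray(d)
        called = d >= 0
        n = called.sum(axis=0).astype(float)  # diploids
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
            h = ((d == 1) & called).sum(axis=0) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    ok = (n1 >= 2) & (n2 >= 2)
    poly = ok & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    if not poly.any():
        return out
    n1, p1, h1 = n1[poly], p1[poly], h1[poly]
    n2, p2, h2 = n2[poly], p2[poly], h2[poly]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / denom
    theta = np.where(denom != 0, theta, np.nan)
    if truncate:
        theta = np.where(np.isnan(theta), np.nan, np.clip(theta, 0.0, None))
        theta = np.where((denom <= 0) & ~np.isnan(theta), 0.0, theta)
    out[poly] = theta
    return out


def running_median(values: np.ndarray, width: int = 31) -> np.ndarray:
    """Centered running median with symmetrically shrinking end windows.

    At position i the window is the largest odd width <= ``width`` that
    fits symmetrically (width 1 at the chromosome's first/last SNP).
    NaN values are excluded from each window's median; an all-NaN window
    yields NaN.  Apply per chromosome.
    """
    if width % 2 == 0:
        raise ValueError("running-median width must be odd")
    x = np.asarray(values, dtype=float)
    n = len(x)
    half = width // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        win = x[i - k : i + k + 1]
        good = win[~np.isnan(win)]
        out[i] = np.median(good) if len(good) else np.nan
    return out


def _hap_group_rows(hap: HaplotypeMatrix, samples: list[str]) -> np.ndarray:
    pos = [hap.samples.index(s) for s in samples]
    return np.ravel([(2 * i, 2 * i + 1) for i in pos])


def compute_group_stats(
    hap: HaplotypeMatrix,
    groups: dict[str, str],
    focal_group: str,
    spec: WindowSpec | None = None,
    fst_sites: "set[str] | None" = None,
) -> pd.DataFrame:
    """Full five-statistic panel for one focal group.

    H12/H2-H1, Tajima's D and pi are computed on the focal group's
    haplotypes over every input site (the lightly filtered phased
    track); FST contrasts the focal group against all remaining
    samples pooled.  When ``fst_sites`` (a set of snp_ids, typically
    the survivors of a stricter common-variant QC) is given, FST and
    its running median are computed on that site domain only and
    joined back by snp_id: rare variants carry almost no
    allele-frequency information and would otherwise drown the FST
    median.  Rows outside the FST domain carry missing FST.  Returns a
    StatPanel-style frame, one row per SNP of the input.
    """
    spec = spec or WindowSpec()
    focal_samples = [s for s in hap.samples if groups.get(s) == focal_group]
    rest_samples = [s for s in hap.samples if groups.get(s) != focal_group]
    if len(focal_samples) < 2:
        raise ValueError(f"group {focal_group!r} needs >= 2 samples")
    if len(rest_samples) < 2:
        raise ValueError("FST contrast needs >= 2 samples outside the focal group")
    rows = _hap_group_rows(hap, focal_samples)
    sub = hap.haplotypes[rows]
    variants = hap.variants

    panel = variants[["snp_id", "chrom", "pos"]].copy()
    alt = sub.sum(axis=0).astype(float)
    called = np.full(hap.n_sites, float(sub.shape[0]))

    # pi lives on the group-polymorphic domain (the per-group file with a
    # minimal MAF filter): group-monomorphic sites would otherwise pile a
    # huge tie block at pi = 0 and flatten the left-tail ranks.
    pi_all = site_pi(alt, called)
    focal_poly = (alt > 0) & (alt < sub.shape[0])
    panel["pi_raw"] = np.where(focal_poly, pi_all, np.nan)
    rest_rows = _hap_group_rows(hap, rest_samples)
    rest_hap = hap.haplotypes[rest_rows]
    focal_dos = (sub[0::2] + sub[1::2]).astype(np.int8)
    rest_dos = (rest_hap[0::2] + rest_hap[1::2]).astype(np.int8)
    if fst_sites is None:
        dom = np.arange(hap.n_sites)
    else:
        dom = np.nonzero(variants["snp_id"].isin(fst_sites).to_numpy())[0]
    fst_raw = np.full(hap.n_sites, np.nan)
    fst_raw[dom] = wc_fst(focal_dos[:, dom], rest_dos[:, dom])
    fst_smooth = np.full(hap.n_sites, np.nan)
    for _, idx in variants.groupby("chrom", sort=False).groups.items():
        idx = np.intersect1d(np.asarray(idx), dom)
        if len(idx):
            fst_smooth[idx] = running_median(fst_raw[idx], spec.smooth_snps)
    panel["fst_raw"] = fst_raw
    panel["fst_smoothed"] = fst_smooth

    h12_col = np.full(hap.n_sites, np.nan)
    h2h1_col = np.full(hap.n_sites, np.nan)
    d_col = np.full(hap.n_sites, np.nan)
    windows = sliding_windows(variants, spec)
    if len(windows):
        for chrom, wsub in windows.groupby("chrom", sort=False):
            starts = wsub["start_idx"].to_numpy()
            anchors = wsub["anchor_idx"].to_numpy()
            h1s, h12s, h2h1s = _garud_windows(sub, starts, spec.window_snps)
            h12_col[anchors] = h12s
            h2h1_col[anchors] = h2h1s
            d_col[anchors] = _tajima_windows(alt, called, starts, spec.window_snps)
    panel["h12"] = h12_col
    panel["h2h1"] = h2h1_col
    panel["tajimas_d"] = d_col

    pi_smooth = np.full(hap.n_sites, np.nan)
    pi_dom = np.nonzero(focal_poly)[0]
    for _, idx in variants.groupby("chrom", sort=False).groups.items():
        idx = np.intersect1d(np.asarray(idx), pi_dom)
        if len(idx):
            pi_smooth[idx] = running_median(
                panel["pi_raw"].to_numpy()[idx], spec.smooth_snps
            )
    panel["pi_smoothed"] = pi_smooth
    return panel


def build_stat_panel(per_stat: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join independently computed statistic tables by snp_id.

    Each value frame must carry ``snp_id`` plus its statistic columns;
    SNPs absent from a frame get NaN for that statistic.  The union of
    SNP ids, in (chrom, pos) order from the first frame that knows the
    SNP, defines the row order.  Duplicate snp_id in any input is an
    error.
    """
    base = None
    for name, df in per_stat.items():
        if df["snp_id"].duplicated().any():
            raise ValueError(f"duplicated snp_id in statistic table {name!r}")
        cols = [c for c in df.columns if c not in ("chrom", "pos")]
        piece = df[["snp_id", "chrom", "pos"] + [c for c in cols if c != "snp_id"]] \
            if {"chrom", "pos"} <= set(df.columns) else df[["snp_id"] + [c for c in cols if c != "snp_id"]]
        if base is None:
            base = piece
        else:
            overlap = [c for c in piece.columns if c != "snp_id" and c in base.columns]
            base = base.merge(piece.drop(columns=overlap), on="snp_id", how="outer")
    if base is None:
        raise ValueError("no statistic tables given")
    if {"chrom", "pos"} <= set(base.columns):
        base = base.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    missing_any = base.drop(columns=["snp_id", "chrom", "pos"], errors="ignore").isna()
    if len(base) and missing_any.all(axis=None):
        warnings.warn("statistic tables share no SNPs: panel is all-missing")
    return base
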