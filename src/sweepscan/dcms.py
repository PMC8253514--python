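"""Decorrelated Composite of Multiple Signals (DCMS).

Each statistic is converted to a one-tailed empirical p-value by
genome-wide ranking (right tail for H2/H1, H12 and FST; left tail for
pi and Tajima's D).  A robust 5x5 correlation matrix is estimated from
a random sample of complete panel rows with the Minimum Covariance
Determinant (FAST-MCD, alpha = 0.75 by default).  The composite is

    DCMS_i = sum_s log10((1 - p_si) / p_si) / w_s,
    w_s    = sum_t |r_st|   (diagonal included),

so statistics that are correlated with many others are down-weighted.
DCMS values are fitted to a normal distribution by a robust (Huber)
Q-Q regression; upper-tail normal p-values are FDR-adjusted to
q-values (Storey's method, BH fallback at small n).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: statistic column -> tail in which selection lies
DEFAULT_TAILS = {
    "h2h1": "right",
    "h12": "right",
    "fst_smoothed": "right",
    "pi_smoothed": "left",
    "tajimas_d": "left",
}


@dataclass
class DcmsConfig:
    """Tunables of the composite step (defaults follow common practice
    for genome-scale scans; covariance_sample_size is capped at the
    number of complete rows available)."""

    covariance_sample_size: int = 300_000
    mcd_alpha: float = 0.75
    q_boundary: float = 0.2
    q_strong: float = 0.01
    seed: int = 0
    tails: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TAILS))

    def __post_init__(self) -> None:
        if not 0.5 <= self.mcd_alpha <= 1.0:
            raise ValueError("mcd_alpha must be in [0.5, 1]")
        for name in ("q_boundary", "q_strong"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if self.q_strong > self.q_boundary:
            raise ValueError("q_strong must be <= q_boundary")
        for tail in self.tails.values():
            if tail not in ("left", "right"):
                raise ValueError(f"tail must be 'left' or 'right', got {tail!r}")


def rank_to_pvalue(values: np.ndarray, tail: str) -> np.ndarray:
    """Empirical one-tailed p by genome-wide ranking.

    Right tail: p_i = #{j : x_j >= x_i} / n over the non-missing values;
    left tail mirrors with <=.  Missing in, missing out; p in [1/n, 1].
    """
    if tail not in ("left", "right"):
        raise ValueError("tail must be 'left' or 'right'")
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    good = ~np.isnan(x)
    n = int(good.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing values to rank")
    xs = np.sort(x[good])
    if xs[0] == xs[-1]:
        warnings.warn("statistic is constant: all empirical p = 1")
        out[good] = 1.0
        return out
    if tail == "right":
        # count of values >= x_i
        cnt = n - np.searchsorted(xs, x[good], side="left")
    else:
        cnt = np.searchsorted(xs, x[good], side="right")
    out[good] = cnt / n
    return out


def _cov_det(x: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    sub = x[rows]
    mu = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    return mu, cov, float(np.linalg.det(cov))


def _c_step(x: np.ndarray, mu: np.ndarray, cov: np.ndarray, h: int) -> np.ndarray:
    inv = np.linalg.pinv(cov)
    d = x - mu
    md = np.einsum("ij,jk,ik->i", d, inv, d)
    return np.argsort(md, kind="stable")[:h]


def fast_mcd(
    x: np.ndarray,
    alpha: float = 0.75,
    seed: int = 0,
    n_starts: int = 500,
    n_keep: int = 10,
    max_c_steps: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum Covariance Determinant location/scatter via FAST-MCD.

    Random elemental (p+1)-subsets are inflated by one C-step pair;
    the ``n_keep`` most promising candidates are iterated to
    convergence and the h-subset with the smallest covariance
    determinant wins (h = ceil(alpha * n)).  Returns (mean, covariance,
    h-subset indices); the raw MCD scatter is returned without a
    consistency factor, which cancels in the derived correlation.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    h = int(np.ceil(alpha * n))
    if h <= p:
        raise ValueError(f"h={h} must exceed dimension {p}; need more rows")
    if h == n:
        mu, cov, _ = _cov_det(x, np.arange(n))
        return mu, cov, np.arange(n)
    rng = np.random.default_rng(seed)

    candidates = []
    attempts = 0
    while len(candidates) < n_starts and attempts < 10 * n_starts:
        attempts += 1
        elem = rng.choice(n, size=p + 1, replace=False)
        mu, cov, det = _cov_det(x, elem)
        if not np.isfinite(det) or det <= 0:
            continue
        rows = _c_step(x, mu, cov, h)
        mu, cov, det = _cov_det(x, rows)
        if not np.isfinite(det) or det <= 0:
            continue
        rows = _c_step(x, mu, cov, h)
        mu, cov, det = _cov_det(x, rows)
        candidates.append((det, rows, mu, cov))
    if not candidates:
        raise RuntimeError(
            "FAST-MCD: all elemental starts produced singular covariances"
        )
    candidates.sort(key=lambda t: t[0])

    best = None
    for det, rows, mu, cov in candidates[:n_keep]:
        prev_det = det
        for _ in range(max_c_steps):
            rows = _c_step(x, mu, cov, h)
            mu, cov, det = _cov_det(x, rows)
            if det <= 0 or abs(prev_det - det) <= 1e-12 * max(prev_det, 1e-300):
                break
            prev_det = det
        if best is None or det < best[0]:
            best = (det, np.sort(rows), mu, cov)
    _, rows, mu, cov = best
    return mu, cov, rows


def exhaustive_mcd(x: np.ndarray, alpha: float = 0.75) -> tuple[float, np.ndarray]:
    """Exact MCD by enumerating every h-subset (tiny n only)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    h = int(np.ceil(alpha * n))
    best_det, best_rows = np.inf, None
    for comb in itertools.combinations(range(n), h):
        _, _, det = _cov_det(x, np.asarray(comb))
        if det < best_det:
            best_det, best_rows = det, np.asarray(comb)
    return best_det, best_rows


def robust_correlation(
    panel: pd.DataFrame,
    stat_columns: list[str],
    sample_size: int,
    alpha: float,
    seed: int,
) -> pd.DataFrame:
    """MCD correlation matrix of the statistics from sampled complete rows.

    Rows with any missing statistic are excluded; min(sample_size,
    available) rows are sampled without replacement under the seed.
    """
    complete = panel[stat_columns].dropna()
    if len(complete) < 50:
        raise ValueError(
            f"only {len(complete)} complete rows; need >= 50 for a stable "
            "covariance estimate — provide more SNPs"
        )
    rng = np.random.default_rng(seed)
    k = min(sample_size, len(complete))
    rows = rng.choice(len(complete), size=k, replace=False)
    x = complete.to_numpy()[rows]
    _, cov, _ = fast_mcd(x, alpha=alpha, seed=int(rng.integers(2**31)))
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return pd.DataFrame(corr, index=stat_columns, columns=stat_columns)


def dcms_score(pvalues: pd.DataFrame, correlation: pd.DataFrame) -> np.ndarray:
    """The composite: sum over statistics of log10((1-p)/p) / w_s.

    ``pvalues`` columns must match the correlation's order.  p is
    clamped to [1/(n+1), n/(n+1)] to keep the log-odds finite; rows with
    any missing p get a missing DCMS.
    """
    cols = list(correlation.columns)
    if set(cols) - set(pvalues.columns):
        raise ValueError("p-value columns do not match correlation matrix")
    p = pvalues[cols].to_numpy(dtype=float)
    # keep the log-odds finite: empirical p can equal 1 exactly (and never
    # falls below 1/n), so only the boundary values are clipped, per
    # statistic with its own ranking depth
    n_col = np.maximum((~np.isnan(p)).sum(axis=0), 1).astype(float)
    pc = p.copy()
    hi = n_col / (n_col + 1.0)
    lo = 1.0 / (n_col + 1.0)
    pc = np.where(pc >= 1.0, hi, pc)
    pc = np.where(pc <= 0.0, lo, pc)
    w = np.abs(correlation.to_numpy()).sum(axis=0)
    terms = np.log10((1.0 - pc) / pc) / w
    score = terms.sum(axis=1)
    score[np.isnan(p).any(axis=1)] = np.nan
    return score


def fit_normal_pvalues(dcms: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Robust normal fit of DCMS; returns (upper-tail p, mu, sigma).

    Ordered DCMS values are regressed on standard-normal plotting
    quantiles with a Huber M-estimator (intercept = mu, slope = sigma),
    then p_i = 1 - Phi((DCMS_i - mu) / sigma).
    """
    import statsmodels.api as sm

    x = np.asarray(dcms, dtype=float)
    good = ~np.isnan(x)
    n = int(good.sum())
    if n < 100:
        raise ValueError(f"need >= 100 DCMS values for the normal fit, got {n}")
    xs = np.sort(x[good])
    if xs[0] == xs[-1]:
        raise ValueError("DCMS is constant: robust scale is zero")
    q = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    design = sm.add_constant(q)
    fit = sm.RLM(xs, design, M=sm.robust.norms.HuberT()).fit()
    mu, sigma = float(fit.params[0]), float(fit.params[1])
    if sigma <= 0:
        raise ValueError(f"robust scale must be positive, got {sigma}")
    p = np.full(x.shape, np.nan)
    p[good] = sps.norm.sf((x[good] - mu) / sigma)
    return p, mu, sigma


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate with a cubic smoother.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) on the grid
    0.05..0.95; a natural cubic smoothing spline (3 effective df,
    approximated by a cubic polynomial fit) is evaluated at the largest
    lambda and clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    n = len(p)
    pi0_l = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return min(max(pi0, 1.0 / n), 1.0)


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """FDR q-values: Storey (pi0-estimated) or plain Benjamini-Hochberg.

    With fewer than 20 p-values Storey's pi0 is unstable; the method
    falls back to BH with a warning.
    """
    if method not in ("storey", "bh"):
        raise ValueError("method must be 'storey' or 'bh'")
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    good = ~np.isnan(p)
    pv = p[good]
    n = len(pv)
    if n == 0:
        return out
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method == "storey" and n < 20:
        warnings.warn("fewer than 20 p-values: falling back to BH")
        method = "bh"
    pi0 = storey_pi0(pv) if method == "storey" else 1.0
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, None, 1.0)
    res = np.empty(n)
    res[order] = q
    out[good] = res
    return out


def attach_dcms(
    panel: pd.DataFrame, config: DcmsConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full composite step on a statistic panel.

    Adds per-statistic empirical p columns (``p_<stat>``), ``dcms``,
    ``dcms_p`` and ``q`` to a copy of the panel; returns (panel,
    correlation matrix).
    """
    cfg = config or DcmsConfig()
    panel = panel.copy()
    stat_cols = list(cfg.tails)
    for col in stat_cols:
        if col not in panel.columns:
            raise ValueError(f"panel lacks statistic column {col!r}")
        panel[f"p_{col}"] = rank_to_pvalue(panel[col].to_numpy(), cfg.tails[col])
    corr = robust_correlation(
        panel, stat_cols, cfg.covariance_sample_size, cfg.mcd_alpha, cfg.seed
    )
    pcols = panel[[f"p_{c}" for c in stat_cols]].rename(
        columns={f"p_{c}": c for c in stat_cols}
    )
    panel["dcms"] = dcms_score(pcols, corr)
    p_norm, mu, sigma = fit_normal_pvalues(panel["dcms"].to_numpy())
    panel["dcms_p"] = p_norm
    panel["q"] = qvalues(panel["dcms_p"].to_numpy(), method="storey")
    panel.attrs["dcms_fit"] = {"mu": mu, "sigma": sigma}
    return panel, corr
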