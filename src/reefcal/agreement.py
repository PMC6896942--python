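"""Difference-vs-average (Bland-Altman) agreement statistics.

For each site and benthic component the between-method difference
``d = PQ - CPI`` is paired with the average ``a = (PQ + CPI) / 2``, the
average being the best available proxy for the unknown true cover.  Group
summaries carry percentile bootstrap confidence intervals obtained by
resampling *sites* with replacement, the sampling unit of the survey
design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootCI",
    "difference_and_average",
    "group_mean_diff",
    "bootstrap_ci",
    "pearson_with_p",
    "signed_rank_test",
]


@dataclass(frozen=True)
class BootCI:
    """A bootstrap confidence interval for a group mean difference."""

    estimate: float
    lo: float
    hi: float
    B: int
    seed: int
    ci_method: str = "percentile"
    level: float = 0.95


def difference_and_average(pairs: pd.DataFrame) -> pd.DataFrame:
    """Append Bland-Altman coordinates to a paired cover table.

    Adds ``d = pq_cover - cpi_cover`` and ``a = (pq_cover + cpi_cover)/2``
    to each row; arithmetic is exact (no rounding).
    """
    out = pairs.copy()
    out["d"] = out["pq_cover"] - out["cpi_cover"]
    out["a"] = (out["pq_cover"] + out["cpi_cover"]) / 2.0
    return out


def group_mean_diff(
    diffs: pd.DataFrame,
    by: str = "reef_type",
    min_n: int = 2,
) -> pd.DataFrame:
    """Arithmetic mean of d per group (or pooled) with group sizes.

    Parameters
    ----------
    by
        ``"reef_type"`` for per-stratum means or ``"pooled"`` for a single
        mean over all rows.
    min_n
        Groups smaller than this are flagged (column ``small_n``).
    """
    if by == "pooled":
        return pd.DataFrame(
            {
                "group": ["pooled"],
                "n": [len(diffs)],
                "mean_d": [float(diffs["d"].mean())],
                "small_n": [len(diffs) < min_n],
            }
        )
    g = diffs.groupby(by, observed=True)["d"].agg(["size", "mean"])
    return pd.DataFrame(
        {
            "group": g.index.astype(str),
            "n": g["size"].to_numpy(),
            "mean_d": g["mean"].to_numpy(),
            "small_n": (g["size"] < min_n).to_numpy(),
        }
    ).reset_index(drop=True)


def bootstrap_ci(
    values,
    B: int = 9999,
    seed: int = 0,
    level: float = 0.95,
    ci_method: str = "percentile",
) -> BootCI:
    """Bootstrap CI for the mean by resampling values (sites) with replacement.

    Deterministic given ``(values, B, seed, ci_method)``.  ``percentile``
    uses the empirical quantiles of the resampled means; ``bca`` applies
    the bias-corrected-and-accelerated adjustment (jackknife
    acceleration).
    """
    x = np.asarray(values, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if ci_method not in ("percentile", "bca"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    n = x.size
    est = float(x.mean())
    if np.ptp(x) == 0.0:  # all identical -> degenerate interval
        return BootCI(est, est, est, B, seed, ci_method, level)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = x[idx].mean(axis=1)
    alpha = 1.0 - level
    if ci_method == "percentile":
        lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:  # bca
        z0 = stats.norm.ppf(
            np.clip((means < est).mean() + 0.5 * (means == est).mean(),
                    1e-9, 1 - 1e-9)
        )
        jack = (x.sum() - x) / (n - 1)
        dj = jack.mean() - jack
        denom = 6.0 * (dj**2).sum() ** 1.5
        acc = (dj**3).sum() / denom if denom > 0 else 0.0
        zlo, zhi = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
        q = stats.norm.cdf(z0 + (z0 + np.array([zlo, zhi]))
                           / (1.0 - acc * (z0 + np.array([zlo, zhi]))))
        lo, hi = np.quantile(means, q)
    return BootCI(est, float(lo), float(hi), B, seed, ci_method, level)


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson correlation with a two-sided p from the t transform (n-2 df).

    Raises on fewer than 3 points or zero variance in either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def signed_rank_test(
    deltas,
    zero_method: str = "wilcox",
) -> dict:
    """Wilcoxon signed-rank test of median change = 0 (two-sided).

    Exact null distribution for n <= 25 (no ties), normal approximation
    otherwise.  Returns both rank-sum conventions: ``w_plus`` (sum of
    ranks of positive deltas) and ``statistic = min(W+, W-)``.  Exact
    zeros are dropped by default (``wilcox``); ``pratt`` keeps them in the
    ranking.
    """
    x = np.asarray(deltas, dtype=float)
    nz = x[x != 0.0]
    if nz.size == 0:
        raise ValueError("degenerate input: all deltas are zero")
    ranked = x if zero_method == "pratt" else nz
    n_eff = nz.size
    mode = "exact" if (n_eff <= 25 and np.unique(np.abs(nz)).size == nz.size
                       and zero_method == "wilcox") else "approx"
    res = stats.wilcoxon(
        ranked,
        zero_method=zero_method,
        alternative="two-sided",
        method="exact" if mode == "exact" else "approx",
    )
    # ranks of |delta|; under Pratt zeros consume ranks but contribute to
    # neither sum
    r = stats.rankdata(np.abs(ranked))
    w_plus = float(r[ranked > 0].sum())
    w_minus = float(r[ranked < 0].sum())
    return {
        "statistic": float(min(w_plus, w_minus)),
        "w_plus": w_plus,
        "w_minus": w_minus,
        "p": float(res.pvalue),
        "n_effective": int(n_eff),
        "method": mode,
    }
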