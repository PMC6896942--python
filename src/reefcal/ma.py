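"""Major-axis (Model II) regression of CPI on PQ.

When both survey methods carry comparable sampling error, an ordinary
regression of one on the other biases the slope; major-axis regression
instead takes the direction of the leading eigenvector of the 2x2 sample
covariance matrix, minimising perpendicular distances.  Its slope is
symmetric under exchange of the two variables
(``slope(x->y) * slope(y->x) = 1``), which suits a conversion that should
not privilege either method.  Point estimates only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MAFit", "ma_fit", "compare_estimators"]


@dataclass(frozen=True)
class MAFit:
    """Major-axis line cpi = intercept + slope * pq through the centroid."""

    slope: float
    intercept: float
    n: int
    mean_pq: float
    mean_cpi: float
    var_pq: float
    var_cpi: float
    cov: float

    def convert(self, pq):
        return self.intercept + self.slope * np.asarray(pq, dtype=float)


def ma_fit(pq, cpi) -> MAFit:
    """Fit the major axis of the (pq, cpi) scatter.

    The slope is the closed-form leading-eigenvector direction

        b = (s_cc - s_pp + sqrt((s_cc - s_pp)^2 + 4 s_pc^2)) / (2 s_pc)

    taking the sign of the sample covariance; the line passes through the
    centroid.  Zero covariance with equal variances leaves the
    orientation undefined and raises.
    """
    x = np.asarray(pq, dtype=float)
    y = np.asarray(cpi, dtype=float)
    if x.size != y.size:
        raise ValueError("pq and cpi must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a major-axis fit")
    s_pp = float(np.var(x, ddof=1))
    s_cc = float(np.var(y, ddof=1))
    s_pc = float(np.cov(x, y, ddof=1)[0, 1])
    if s_pc == 0.0:
        if s_cc == s_pp:
            raise ValueError("major-axis orientation undefined "
                             "(zero covariance, equal variances)")
        # principal axis aligns with a coordinate axis
        raise ValueError("zero covariance between methods; no meaningful "
                         "conversion slope")
    b = (s_cc - s_pp + np.sqrt((s_cc - s_pp) ** 2 + 4.0 * s_pc**2)) \
        / (2.0 * s_pc)
    a = float(y.mean() - b * x.mean())
    return MAFit(slope=float(b), intercept=a, n=int(x.size),
                 mean_pq=float(x.mean()), mean_cpi=float(y.mean()),
                 var_pq=s_pp, var_cpi=s_cc, cov=s_pc)


def compare_estimators(ma_fits: dict, ancova_rules, pairs: pd.DataFrame,
                       ) -> pd.DataFrame:
    """Converted-cover summaries under the ANCOVA and MA estimators.

    Parameters
    ----------
    ma_fits
        ``{(component, reef_type): MAFit}`` — MA is always fitted stratum
        by stratum.
    ancova_rules
        Iterable of :class:`~reefcal.conversion.ConversionRule`.
    pairs
        Paired covers (``component, reef_type, pq_cover, cpi_cover``).

    Returns one row per stratum with the original PQ mean/SD, each
    estimator's converted mean/SD, and the absolute difference of the two
    converted means.
    """
    lut = {(r.component, r.reef_type): r for r in ancova_rules}
    rows = []
    for (comp, reef), g in pairs.groupby(["component", "reef_type"],
                                         observed=True):
        key = (comp, reef)
        if key not in lut or key not in ma_fits:
            continue
        pq = g["pq_cover"].to_numpy(dtype=float)
        anc = lut[key].convert(pq)
        ma = ma_fits[key].convert(pq)
        rows.append({
            "component": comp,
            "reef_type": reef,
            "n": len(g),
            "original_mean": pq.mean(),
            "original_sd": pq.std(ddof=1) if len(g) > 1 else 0.0,
            "ancova_mean": anc.mean(),
            "ancova_sd": anc.std(ddof=1) if len(g) > 1 else 0.0,
            "ma_mean": ma.mean(),
            "ma_sd": ma.std(ddof=1) if len(g) > 1 else 0.0,
            "abs_mean_diff": abs(anc.mean() - ma.mean()),
        })
    return pd.DataFrame(rows)
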