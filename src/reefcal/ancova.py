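"""Heteroscedastic ANCOVA of between-method cover differences.

The model relates the between-method difference ``d = PQ - CPI`` to reef
type (categorical factor) and the average cover ``a = (PQ + CPI)/2``
(numerical covariate), with their interaction::

    d_i = beta0_{r(i)} + beta1_{r(i)} * a_i + eps_i,
    eps_i ~ N(0, sigma^2 * delta_{r(i)}^2)

Each reef type carries its own residual variance multiplier
``delta_r`` (reference reef type fixed at 1), estimated jointly with the
regression coefficients by restricted maximum likelihood (REML; profiled
over the coefficients and the common scale ``sigma``).  Sequential
(Type I) F-tests with denominator degrees of freedom ``n - p`` summarise
the fit, and backward elimination of non-significant terms (respecting
marginality) yields the most parsimonious model, whose retained terms
determine the bias *scenario class* — the typology that decides which
conversion formula applies between the two survey methods.

The API follows the model / results split of statsmodels:
:class:`DifferenceGLS` holds data and design, ``fit()`` returns a
:class:`DifferenceGLSResults` carrying estimates, their covariance, the
F-table and ``summary()``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScenarioClass",
    "DifferenceGLS",
    "DifferenceGLSResults",
    "fit_gls",
    "reduce_model",
    "classify_scenario",
    "residual_diagnostics",
    "ConvergenceError",
    "DegenerateVarianceError",
]

FULL_TERMS = ("factor", "covariate", "interaction")


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


class DegenerateVarianceError(ValueError):
    """Residual variance is (numerically) zero; F statistics undefined."""


class ScenarioClass(str, enum.Enum):
    """Typology of between-method bias, from the retained model terms.

    * ``NO_DIFFERENCE`` — nothing retained, intercept not significant.
    * ``CONSTANT_POOLED`` — one constant offset for all reef types.
    * ``CONSTANT_BY_REEF`` — constant offsets differing by reef type.
    * ``COMMON_SLOPE_POOLED`` — differences scale with average cover,
      one line for all reef types.
    * ``COMMON_SLOPE_BY_REEF`` — common scaling slope, reef-specific
      intercepts.
    * ``SLOPE_BY_REEF`` — scaling differs among reef types (interaction).
    """

    NO_DIFFERENCE = "NO_DIFFERENCE"
    CONSTANT_POOLED = "CONSTANT_POOLED"
    CONSTANT_BY_REEF = "CONSTANT_BY_REEF"
    COMMON_SLOPE_POOLED = "COMMON_SLOPE_POOLED"
    COMMON_SLOPE_BY_REEF = "COMMON_SLOPE_BY_REEF"
    SLOPE_BY_REEF = "SLOPE_BY_REEF"


def _term_order_key(t):
    return FULL_TERMS.index(t)


class DifferenceGLS:
    """Difference-vs-average model for one benthic component.

    Parameters
    ----------
    d, a : array-like
        Between-method difference and between-method average per site
        (percent cover scale).
    reef_type : array-like of str
        Stratum of each site.
    terms : sequence of {"factor", "covariate", "interaction"}
        Fixed-effect terms beyond the always-present intercept, fitted in
        this sequential order (interaction requires both main terms).
    reference : str, optional
        Reference reef type (variance multiplier fixed at 1, treatment
        coding); default first level alphabetically.
    variance_groups : bool
        Estimate a residual-variance multiplier per reef type (default);
        if False, fit homoscedastic.
    """

    def __init__(self, d, a, reef_type, terms=FULL_TERMS, reference=None,
                 variance_groups=True):
        self.d = np.asarray(d, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.reef_type = np.asarray(reef_type, dtype=object)
        if not (self.d.shape == self.a.shape == self.reef_type.shape):
            raise ValueError("d, a and reef_type must have equal length")
        terms = tuple(sorted(set(terms), key=_term_order_key))
        if "interaction" in terms and not {"factor", "covariate"} <= set(terms):
            raise ValueError("interaction requires both main terms "
                             "(marginality)")
        self.terms = terms
        self.levels = sorted(set(self.reef_type))
        if reference is None:
            reference = self.levels[0]
        if reference not in self.levels:
            raise ValueError(f"reference level {reference!r} not present")
        self.reference = reference
        self.levels = [reference] + [l for l in self.levels if l != reference]
        self.variance_groups = variance_groups and len(self.levels) > 1
        self._validate()

    # -- construction ------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response="d", covariate="a",
                       factor="reef_type", **kwargs) -> "DifferenceGLS":
        """Build from a tidy per-site table (e.g. agreement output)."""
        return cls(df[response], df[covariate], df[factor], **kwargs)

    def _validate(self):
        n = self.d.size
        counts = pd.Series(self.reef_type).value_counts()
        if self.variance_groups and (counts < 2).any():
            raise ValueError(
                "need >= 2 observations per variance group; got "
                f"{counts.to_dict()}"
            )
        if self.variance_groups and (counts < 3).any():
            warnings.warn(
                "group(s) with < 3 observations cannot carry a free "
                "variance multiplier; pooling variances",
                stacklevel=3,
            )
            self.variance_groups = False
        if "covariate" in self.terms and np.ptp(self.a) == 0.0:
            raise ValueError("covariate is constant; drop the covariate term")
        X, _, _ = self._design(self.terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "singular design matrix (e.g. a reef type with a single "
                "site while the interaction is requested)"
            )
        if n <= X.shape[1]:
            raise ValueError("need n > number of parameters")

    # -- design ------------------------------------------------------

    def _design(self, terms):
        """Design matrix in sequential term order.

        Returns (X, column names, term slices).
        """
        n = self.d.size
        cols = [np.ones(n)]
        names = ["Intercept"]
        slices = {"intercept": slice(0, 1)}
        pos = 1
        dummies = {
            l: (self.reef_type == l).astype(float) for l in self.levels[1:]
        }
        for t in terms:
            if t == "factor":
                for l in self.levels[1:]:
                    cols.append(dummies[l])
                    names.append(f"reef_type[{l}]")
                slices[t] = slice(pos, pos + len(self.levels) - 1)
                pos += len(self.levels) - 1
            elif t == "covariate":
                cols.append(self.a)
                names.append("a")
                slices[t] = slice(pos, pos + 1)
                pos += 1
            elif t == "interaction":
                for l in self.levels[1:]:
                    cols.append(dummies[l] * self.a)
                    names.append(f"reef_type[{l}]:a")
                slices[t] = slice(pos, pos + len(self.levels) - 1)
                pos += len(self.levels) - 1
        return np.column_stack(cols), names, slices

    # -- estimation --------------------------------------------------

    def _group_index(self):
        return np.array([self.levels.index(r) for r in self.reef_type])

    @staticmethod
    def _whitened_fit(X, y, sd):
        """Weighted LS given per-observation residual SD multipliers."""
        Xw = X / sd[:, None]
        yw = y / sd
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        return beta, rss, Xw, yw

    def _neg2_profiled(self, log_delta, X, y, gidx, method):
        delta = np.ones(len(self.levels))
        delta[1:] = np.exp(log_delta)
        sd = delta[gidx]
        beta, rss, Xw, _ = self._whitened_fit(X, y, sd)
        n, p = X.shape
        logdetV = 2.0 * np.log(sd).sum()
        log_rss = np.log(max(rss, 1e-300))
        if method == "reml":
            sign, logdetXtX = np.linalg.slogdet(Xw.T @ Xw)
            return (n - p) * log_rss + logdetV + logdetXtX
        return n * log_rss + logdetV

    def fit(self, method: str = "reml", fixed_delta: dict | None = None,
            tol: float = 1e-8, maxiter: int = 200) -> "DifferenceGLSResults":
        """Estimate coefficients and variance structure.

        Parameters
        ----------
        method : {"reml", "ml"}
            Restricted (default) or full maximum likelihood.
        fixed_delta : dict, optional
            Known residual-SD multipliers per reef type (reference must
            map to 1); skips variance estimation — used for oracles and
            for weight-constrained fits.
        """
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        X, names, slices = self._design(self.terms)
        y = self.d
        n, p = X.shape
        gidx = self._group_index()
        converged = True
        n_iter = 0
        if fixed_delta is not None:
            delta = np.array([float(fixed_delta[l]) for l in self.levels])
            if delta[0] != 1.0:
                raise ValueError("reference delta must be 1")
        elif not self.variance_groups:
            delta = np.ones(len(self.levels))
        else:
            # start from OLS residual SD ratios per group
            beta0, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r0 = y - X @ beta0
            if float(r0 @ r0) <= 1e-12 * max(float(y @ y), 1.0):
                # perfect OLS fit: variance ratios are unidentified
                return self._finalize(X, y, np.ones(len(self.levels)),
                                      gidx, method, True, 0)
            sds = np.array([
                max(np.std(r0[gidx == g]), 1e-6)
                for g in range(len(self.levels))
            ])
            x0 = np.log(sds[1:] / sds[0])
            res = optimize.minimize(
                self._neg2_profiled, x0, args=(X, y, gidx, method),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": tol, "maxiter": maxiter * 10,
                         "maxfev": maxiter * 10},
            )
            converged = bool(res.success)
            n_iter = int(res.nit)
            delta = np.ones(len(self.levels))
            delta[1:] = np.exp(res.x)
        return self._finalize(X, y, delta, gidx, method, converged, n_iter)

    def _finalize(self, X, y, delta, gidx, method, converged, n_iter):
        _, names, slices = self._design(self.terms)
        n, p = X.shape
        sd = delta[gidx]
        beta, rss, Xw, yw = self._whitened_fit(X, y, sd)
        dof = n - p if method == "reml" else n
        sigma2 = rss / dof
        XtX = Xw.T @ Xw
        cov = sigma2 * np.linalg.inv(XtX)
        logdetV = 2.0 * np.log(sd).sum()
        _, logdetXtX = np.linalg.slogdet(XtX)
        if rss <= 1e-12 * max(float(yw @ yw), 1.0):
            # perfect fit: estimates are exact, inference is undefined
            # (anova()/bse raise or degenerate downstream)
            sigma2 = 0.0
            llf = np.inf
        elif method == "reml":
            llf = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdetV
                          + logdetXtX + (n - p))
        else:
            llf = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
        return DifferenceGLSResults(
            model=self,
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            delta=dict(zip(self.levels, delta)),
            sigma=float(np.sqrt(sigma2)),
            llf=float(llf),
            method=method,
            converged=converged,
            n_iter=n_iter,
            term_slices=slices,
        )


@dataclass
class DifferenceGLSResults:
    """Fitted heteroscedastic ANCOVA (see :class:`DifferenceGLS`)."""

    model: DifferenceGLS
    params: pd.Series
    cov_params: pd.DataFrame
    delta: dict
    sigma: float
    llf: float
    method: str
    converged: bool
    n_iter: int
    term_slices: dict

    # -- basic quantities --------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.d.size

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.params)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues.to_numpy()
        p = np.where(np.isnan(t), 1.0,
                     2 * stats.t.sf(np.abs(t), self.df_resid))
        return pd.Series(p, index=self.params.index)

    @property
    def fittedvalues(self) -> np.ndarray:
        X, _, _ = self.model._design(self.model.terms)
        return X @ self.params.to_numpy()

    @property
    def resid(self) -> np.ndarray:
        return self.model.d - self.fittedvalues

    @property
    def resid_standardized(self) -> np.ndarray:
        if self.sigma == 0.0:
            return np.zeros_like(self.resid)
        sd = np.array([self.delta[r] for r in self.model.reef_type])
        return self.resid / (self.sigma * sd)

    # -- per-reef coefficients (reference-free reporting) ------------

    def reef_coefficients(self) -> pd.DataFrame:
        """Intercept/slope (beta0_r, beta1_r) of the line d = f(a) per reef.

        Tied coefficients are replicated across reef types when the model
        pools them, so downstream conversion never depends on the
        reference-level choice.
        """
        m = self.model
        b = self.params
        rows = []
        for lvl in sorted(m.levels):
            b0 = b["Intercept"]
            b1 = b["a"] if "covariate" in m.terms else 0.0
            if "factor" in m.terms and lvl != m.reference:
                b0 = b0 + b[f"reef_type[{lvl}]"]
            if "interaction" in m.terms and lvl != m.reference:
                b1 = b1 + b[f"reef_type[{lvl}]:a"]
            rows.append({"reef_type": lvl, "beta0": float(b0),
                         "beta1": float(b1)})
        return pd.DataFrame(rows)

    # -- sequential F table ------------------------------------------

    def anova(self, term_order=None) -> pd.DataFrame:
        """Sequential (Type I) F-table at the fitted variance structure.

        Terms enter in ``term_order`` (default: the model's declared
        order, intercept first); denominator df is ``n - p`` of this
        fitted model.  Reordering does not refit the variance structure
        (the model span is unchanged).
        """
        m = self.model
        if not self.converged:
            raise ConvergenceError("cannot compute F-table: fit did not "
                                   "converge")
        order = tuple(term_order) if term_order is not None else m.terms
        if set(order) != set(m.terms):
            raise ValueError("term_order must be a permutation of the "
                             "fitted terms")
        X, _, slices = m._design(order)
        sd = np.array([self.delta[r] for r in m.reef_type])
        Xw = X / sd[:, None]
        yw = m.d / sd
        Q, R = np.linalg.qr(Xw)
        eff = Q.T @ yw
        sigma2 = self.sigma**2
        if sigma2 <= np.finfo(float).tiny:
            raise DegenerateVarianceError("zero residual variance; "
                                          "F undefined")
        n, p = X.shape
        rows = []
        for t in ("intercept",) + order:
            sl = slices[t]
            df_num = sl.stop - sl.start
            ss = float((eff[sl] ** 2).sum())
            F = (ss / df_num) / sigma2
            rows.append({
                "term": _PRETTY.get(t, t),
                "df_num": df_num,
                "df_den": n - p,
                "F": F,
                "p": float(stats.f.sf(F, df_num, n - p)),
            })
        return pd.DataFrame(rows)

    # -- presentation ------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Heteroscedastic GLS ANCOVA (difference ~ "
            + " + ".join(("1",) + self.model.terms) + ")",
            f"method: {self.method.upper()}   n: {self.nobs}   "
            f"p: {len(self.params)}   df_resid: {self.df_resid}   "
            f"logLik: {self.llf:.3f}",
            "",
            "Coefficients:",
        ]
        tab = pd.DataFrame({
            "estimate": self.params,
            "std_error": self.bse,
            "t": self.tvalues,
            "p": self.pvalues,
        })
        lines.append(tab.to_string(float_format=lambda v: f"{v:10.4f}"))
        lines.append("")
        lines.append("Residual SD multipliers (reference = 1): "
                     + ", ".join(f"{k}={v:.4f}"
                                 for k, v in self.delta.items()))
        lines.append(f"Residual scale sigma: {self.sigma:.4f}")
        lines.append("")
        lines.append("Sequential F-tests:")
        lines.append(self.anova().to_string(
            index=False, float_format=lambda v: f"{v:9.4f}"))
        return "\n".join(lines)


_PRETTY = {
    "intercept": "Intercept",
    "factor": "Reef type",
    "covariate": "Average cover",
    "interaction": "Reef type x Average cover",
}


# ---------------------------------------------------------------------------
# functional conveniences


def fit_gls(data: pd.DataFrame, terms=FULL_TERMS,
            **kwargs) -> DifferenceGLSResults:
    """Fit the difference-vs-average ANCOVA from a tidy per-site table."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("method", "fixed_delta", "tol",
                                             "maxiter") if k in kwargs}
    return DifferenceGLS.from_dataframe(data, terms=terms,
                                        **kwargs).fit(**fit_kwargs)


def _last_term_p(results: DifferenceGLSResults, term: str) -> float:
    """p-value of *term* when it enters the sequential decomposition last."""
    order = tuple(t for t in results.model.terms if t != term) + (term,)
    tab = results.anova(term_order=order)
    return float(tab.loc[tab.index[-1], "p"])


def reduce_model(data: pd.DataFrame, alpha: float = 0.05,
                 **model_kwargs) -> tuple[DifferenceGLSResults, list[dict]]:
    """Backward-eliminate non-significant terms (marginality respected).

    Starting from the full model (factor + covariate + interaction), each
    removable term (one not contained in a retained higher-order term) is
    tested by its sequential F when ordered last; the least significant
    term with p > alpha is dropped and the model refitted, until all
    retained terms are significant.  The intercept is always retained.

    Returns the final fit and the elimination trace (one record per
    tested step).
    """
    terms = list(FULL_TERMS)
    trace: list[dict] = []
    while True:
        res = fit_gls(data, terms=tuple(terms), **model_kwargs)
        if not res.converged:
            raise ConvergenceError("model reduction: fit did not converge")
        removable = [t for t in terms
                     if not (t in ("factor", "covariate")
                             and "interaction" in terms)]
        if not removable:
            return res, trace
        pvals = {t: _last_term_p(res, t) for t in removable}
        worst = max(pvals, key=pvals.get)
        trace.append({"terms": tuple(terms), "tested": dict(pvals),
                      "dropped": worst if pvals[worst] > alpha else None})
        if pvals[worst] <= alpha:
            return res, trace
        terms.remove(worst)


def classify_scenario(results: DifferenceGLSResults,
                      alpha: float = 0.05) -> ScenarioClass:
    """Map the retained terms of a reduced fit to its bias scenario class."""
    terms = set(results.model.terms)
    if "interaction" in terms:
        return ScenarioClass.SLOPE_BY_REEF
    if "covariate" in terms:
        return (ScenarioClass.COMMON_SLOPE_BY_REEF if "factor" in terms
                else ScenarioClass.COMMON_SLOPE_POOLED)
    if "factor" in terms:
        return ScenarioClass.CONSTANT_BY_REEF
    if float(results.pvalues["Intercept"]) <= alpha:
        return ScenarioClass.CONSTANT_POOLED
    return ScenarioClass.NO_DIFFERENCE


def residual_diagnostics(results: DifferenceGLSResults,
                         band=(0.5, 1.5)) -> dict:
    """Per-group standardized-residual spread, to judge the variance model.

    When the variance structure is adequate each group's standardized
    residual SD is near 1.  Groups outside ``band`` are flagged; the
    heterogeneity ratio is max/min group SD.
    """
    z = results.resid_standardized
    groups = pd.Series(results.model.reef_type)
    out = {}
    for lvl, idx in groups.groupby(groups).groups.items():
        zi = z[np.asarray(idx)]
        sd = float(np.std(zi, ddof=1)) if zi.size > 1 else 0.0
        out[lvl] = sd
    sds = np.array([v for v in out.values()])
    positive = sds[sds > 0]
    ratio = (float(positive.max() / positive.min()) if positive.size
             else float("nan"))
    return {
        "group_sd": out,
        "heterogeneity_ratio": ratio,
        "flagged": sorted(l for l, s in out.items()
                          if not band[0] <= s <= band[1]),
        "degenerate": bool((sds == 0).any()),
    }
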