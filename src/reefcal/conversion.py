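"""PQ -> CPI conversion rules derived from the fitted difference model.

If the between-method difference follows the line

    PQ - CPI = beta0 + beta1 * (PQ + CPI) / 2

then, solving for CPI, the photoquadrat estimate converts directly to a
chain point-intercept one through

    CPI = a + b * PQ,
    a = -beta0 / (1 + beta1/2),
    b = (1 - beta1/2) / (1 + beta1/2),

which is singular at beta1 = -2.  Rules are derived from the reduced
ANCOVA's per-reef coefficients; tied coefficients are replicated across
reef types whenever the reduced model pools them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ancova import DifferenceGLSResults, ScenarioClass

__all__ = [
    "ConversionRule",
    "SingularConversionError",
    "invert_difference_model",
    "difference_coefficients",
    "build_rules",
    "apply_rules",
    "roundtrip_validate",
]

_SING_TOL = 1e-9


class SingularConversionError(ValueError):
    """beta1 = -2: the difference line cannot be inverted."""


def invert_difference_model(beta0: float, beta1: float,
                            label: str = "") -> tuple[float, float]:
    """Invert difference-line coefficients into the conversion line (a, b).

    Exact arithmetic; raises :class:`SingularConversionError` when
    ``1 + beta1/2`` vanishes (within 1e-9).
    """
    den = 1.0 + beta1 / 2.0
    if abs(den) <= _SING_TOL:
        raise SingularConversionError(
            f"beta1 = {beta1} is singular (beta1 -> -2)"
            + (f" for {label}" if label else "")
        )
    a = -beta0 / den
    b = (1.0 - beta1 / 2.0) / den
    return a, b


def difference_coefficients(a: float, b: float) -> tuple[float, float]:
    """Recover (beta0, beta1) from a conversion line CPI = a + b*PQ.

    Exact inverse of :func:`invert_difference_model`; singular at b = -1.
    """
    if abs(1.0 + b) <= _SING_TOL:
        raise SingularConversionError(f"conversion slope b = {b} is singular")
    beta1 = 2.0 * (1.0 - b) / (1.0 + b)
    beta0 = -a * (1.0 + beta1 / 2.0)
    return beta0, beta1


@dataclass(frozen=True)
class ConversionRule:
    """The line CPI = intercept + slope * PQ for one component x reef type."""

    component: str
    reef_type: str
    intercept: float
    slope: float
    scenario_class: str
    n_sites: int = 0
    source: str = ""

    def __post_init__(self):
        if not np.isfinite(self.intercept) or not np.isfinite(self.slope):
            raise ValueError("non-finite conversion coefficients")

    @property
    def valid(self) -> bool:
        """A non-positive slope is never applied as a conversion."""
        return self.slope > 0.0

    def convert(self, pq):
        return self.intercept + self.slope * np.asarray(pq, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionRule":
        return cls(**d)


def build_rules(results: DifferenceGLSResults, component: str,
                scenario: ScenarioClass | None = None,
                alpha: float = 0.05) -> list[ConversionRule]:
    """Derive one conversion rule per reef type from a reduced fit.

    ``NO_DIFFERENCE`` yields the identity rule (a=0, b=1) — converting
    through a non-significant constant would only add noise.  Rules with
    non-positive slope are returned but marked invalid (``rule.valid``);
    they are never silently applied.
    """
    from .ancova import classify_scenario

    if not results.converged:
        raise ValueError("cannot build rules from a non-converged fit")
    if scenario is None:
        scenario = classify_scenario(results, alpha=alpha)
    coefs = results.reef_coefficients()
    rules = []
    for _, row in coefs.iterrows():
        if scenario is ScenarioClass.NO_DIFFERENCE:
            a, b = 0.0, 1.0
        else:
            a, b = invert_difference_model(
                row["beta0"], row["beta1"],
                label=f"{component}/{row['reef_type']}",
            )
        rules.append(ConversionRule(
            component=component,
            reef_type=str(row["reef_type"]),
            intercept=float(a),
            slope=float(b),
            scenario_class=scenario.value,
            n_sites=int((results.model.reef_type == row["reef_type"]).sum()),
            source=f"gls-{results.method}",
        ))
    return rules


def apply_rules(rules, pq_covers: pd.DataFrame,
                clamp: bool = False) -> pd.DataFrame:
    """Convert PQ percent covers with the matching (component, reef) rule.

    Input rows need ``reef_type, component`` and a cover column
    (``cover`` or ``pq_cover``).  Output adds ``converted`` plus a
    ``flag`` column marking conversions outside [0, 100]; out-of-range
    values are kept raw unless ``clamp=True`` (display only — clamping
    would bias round-trip validation).

    Raises ``KeyError`` listing every (component, reef_type) pair without
    a rule, and ``ValueError`` if a matched rule has non-positive slope.
    """
    lut = {(r.component, r.reef_type): r for r in rules}
    col = "pq_cover" if "pq_cover" in pq_covers.columns else "cover"
    need = set(zip(pq_covers["component"], pq_covers["reef_type"]))
    gaps = sorted(k for k in need if k not in lut)
    if gaps:
        raise KeyError(f"no conversion rule for: {gaps}")
    invalid = sorted({k for k in need if not lut[k].valid})
    if invalid:
        raise ValueError(
            f"rule(s) with non-positive slope cannot be applied: {invalid}"
        )
    out = pq_covers.copy()
    keys = list(zip(out["component"], out["reef_type"]))
    a = np.array([lut[k].intercept for k in keys])
    b = np.array([lut[k].slope for k in keys])
    conv = a + b * out[col].to_numpy(dtype=float)
    out["converted"] = np.clip(conv, 0.0, 100.0) if clamp else conv
    out["flag"] = (conv < 0.0) | (conv > 100.0)
    out["converted_from"] = [f"{k[0]}/{k[1]}" for k in keys]
    return out


def roundtrip_validate(rules, pairs: pd.DataFrame,
                       alpha: float = 0.05) -> dict:
    """Check that conversion removes the systematic bias it models.

    PQ covers are converted with ``rules``, differences recomputed
    against CPI, and the full ANCOVA refitted on the converted pairs.
    Reported per reef type: mean residual difference with a 95% t-interval
    and the fitted slope with a 95% Wald interval.  ``passed`` is True
    when zero lies inside every interval.
    """
    from . import agreement
    from .ancova import fit_gls
    from scipy import stats

    conv = apply_rules(rules, pairs)
    post = pairs.copy()
    post["pq_cover"] = conv["converted"].to_numpy()
    diffs = agreement.difference_and_average(post)
    report = {"groups": {}, "passed": True, "means_passed": True,
              "slopes_passed": True}
    for lvl, g in diffs.groupby("reef_type", observed=True):
        d = g["d"].to_numpy()
        m = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
        tcrit = stats.t.ppf(1 - alpha / 2, max(d.size - 1, 1))
        lo, hi = m - tcrit * se, m + tcrit * se
        ok = bool(lo <= 0.0 <= hi)
        report["groups"][str(lvl)] = {
            "mean_d": m, "lo": lo, "hi": hi, "n": int(d.size),
            "zero_inside": bool(ok),
        }
        report["passed"] &= ok
        report["means_passed"] &= ok
    if np.ptp(diffs["a"].to_numpy()) > 0:
        res = fit_gls(diffs)
        tcrit = stats.t.ppf(1 - alpha / 2, res.df_resid)
        slopes = {}
        for _, row in res.reef_coefficients().iterrows():
            # Wald interval on the per-reef slope via the delta of params
            lvl = row["reef_type"]
            names = ["a"]
            if lvl != res.model.reference:
                names.append(f"reef_type[{lvl}]:a")
            names = [n for n in names if n in res.params.index]
            var = float(
                np.ones(len(names))
                @ res.cov_params.loc[names, names].to_numpy()
                @ np.ones(len(names))
            )
            se = np.sqrt(var)
            lo, hi = row["beta1"] - tcrit * se, row["beta1"] + tcrit * se
            ok = bool(lo <= 0.0 <= hi)
            slopes[str(lvl)] = {"slope": float(row["beta1"]), "lo": float(lo),
                                "hi": float(hi), "zero_inside": bool(ok)}
            report["passed"] &= ok
            report["slopes_passed"] &= ok
        report["slopes"] = slopes
    return report
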