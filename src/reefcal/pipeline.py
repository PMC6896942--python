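"""End-to-end orchestration: compare methods, derive and validate
conversions, simulate, and run temporal change analyses."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, io, ma, simulate
from .ancova import classify_scenario, reduce_model, residual_diagnostics
from .conversion import apply_rules, build_rules, roundtrip_validate

__all__ = ["PipelineConfig", "ComponentReport", "run_compare",
           "run_simulate", "run_temporal"]

log = logging.getLogger("reefcal")


@dataclass
class PipelineConfig:
    """Tunable options of a comparison run."""

    alpha: float = 0.05
    B: int = 9999
    seed: int = 0
    ci_method: str = "percentile"
    estimation: str = "reml"
    clamp: bool = False
    min_group_n: int = 2
    continue_on_error: bool = True
    outdir: str | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ComponentReport:
    """Everything the pipeline derives for one benthic component."""

    component: str
    diffs: pd.DataFrame
    group_summary: pd.DataFrame
    f_table: pd.DataFrame
    trace: list
    scenario: str
    rules: list
    roundtrip: dict
    diagnostics: dict
    ma_comparison: pd.DataFrame
    error: str | None = None


def _group_summary(diffs: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    groups = [(r, g["d"].to_numpy())
              for r, g in diffs.groupby("reef_type", observed=True)]
    groups.append(("pooled", diffs["d"].to_numpy()))
    for name, vals in groups:
        ci = agreement.bootstrap_ci(vals, B=cfg.B, seed=cfg.seed,
                                    ci_method=cfg.ci_method)
        rows.append({"group": name, "n": len(vals), "mean_d": ci.estimate,
                     "lo": ci.lo, "hi": ci.hi, "B": ci.B, "seed": ci.seed})
    return pd.DataFrame(rows)


def run_compare(pairs: pd.DataFrame,
                config: PipelineConfig | None = None) -> dict:
    """Full method-comparison analysis, one report per benthic component.

    For each component: difference/average table, per-reef and pooled
    mean differences with bootstrap CIs, Pearson screening, the full
    sequential F-table, backward reduction with trace, scenario class,
    conversion rules, round-trip validation and the MA-regression
    comparison.  Components failing with a hard error are reported and
    skipped when ``config.continue_on_error``.
    """
    cfg = config or PipelineConfig()
    if pairs.empty:
        raise ValueError("no paired data")
    reports: dict[str, ComponentReport] = {}
    for comp, g in pairs.groupby("component", observed=True):
        try:
            reports[comp] = _compare_component(comp, g, cfg)
        except Exception as exc:  # noqa: BLE001 - component-scoped recovery
            log.error("component %s failed: %s", comp, exc)
            if not cfg.continue_on_error:
                raise
            reports[comp] = ComponentReport(
                component=comp, diffs=pd.DataFrame(),
                group_summary=pd.DataFrame(), f_table=pd.DataFrame(),
                trace=[], scenario="", rules=[], roundtrip={},
                diagnostics={}, ma_comparison=pd.DataFrame(),
                error=str(exc),
            )
    if cfg.outdir:
        _write_bundle(reports, cfg)
    return reports


def _compare_component(comp: str, g: pd.DataFrame,
                       cfg: PipelineConfig) -> ComponentReport:
    diffs = agreement.difference_and_average(g)
    summary = _group_summary(diffs, cfg)
    r, p, n = agreement.pearson_with_p(g["pq_cover"], g["cpi_cover"])
    full = None
    from .ancova import fit_gls
    full = fit_gls(diffs, method=cfg.estimation)
    f_table = full.anova()
    reduced, trace = reduce_model(diffs, alpha=cfg.alpha,
                                  method=cfg.estimation)
    scenario = classify_scenario(reduced, alpha=cfg.alpha)
    rules = build_rules(reduced, comp, scenario, alpha=cfg.alpha)
    rt = roundtrip_validate(rules, g, alpha=cfg.alpha)
    diag = residual_diagnostics(full)
    diag["pearson"] = {"r": r, "p": p, "n": n}
    ma_fits = {}
    for reef, gg in g.groupby("reef_type", observed=True):
        try:
            ma_fits[(comp, reef)] = ma.ma_fit(gg["pq_cover"],
                                              gg["cpi_cover"])
        except ValueError:
            pass
    comparison = ma.compare_estimators(ma_fits, rules, g)
    return ComponentReport(
        component=comp, diffs=diffs, group_summary=summary,
        f_table=f_table, trace=trace, scenario=scenario.value, rules=rules,
        roundtrip=rt, diagnostics=diag, ma_comparison=comparison,
    )


def _write_bundle(reports: dict, cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_rules = []
    for comp, rep in reports.items():
        if rep.error:
            continue
        rep.diffs.to_csv(out / f"{comp}_diffs.csv", index=False)
        rep.group_summary.to_csv(out / f"{comp}_summary.csv", index=False)
        rep.f_table.to_csv(out / f"{comp}_ftable.csv", index=False)
        if len(rep.ma_comparison):
            rep.ma_comparison.to_csv(out / f"{comp}_ma_comparison.csv",
                                     index=False)
        all_rules.extend(rep.rules)
    io.write_conversion_rules(all_rules, out / "conversion_rules.json")
    meta = {
        "config": cfg.to_dict(),
        "components": {
            comp: {
                "scenario": rep.scenario,
                "roundtrip_passed": rep.roundtrip.get("passed"),
                "trace": [
                    {**t, "terms": list(t["terms"])} for t in rep.trace
                ],
                "error": rep.error,
            }
            for comp, rep in reports.items()
        },
    }
    meta["config_hash"] = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2,
                                                      sort_keys=True))


def run_simulate(kind: str = "site", seed: int = 0, spec=None,
                 outdir: str | None = None):
    """Generate a synthetic dataset bundle (deterministic per seed).

    ``kind='site'`` writes a site-level cover table plus the generating
    truth; ``kind='plot'`` realizes one plot mosaic and samples both
    protocols into point records.
    """
    if kind == "site":
        spec = spec or simulate.study_spec()
        covers, truth = simulate.gen_site_level(spec, seed=seed)
        bundle = {"covers": covers, "truth": truth}
    elif kind == "plot":
        spec = spec or PlotDefaults()
        plot = simulate.gen_plot(spec, seed=seed)
        cpi = simulate.sample_cpi(plot, seed=seed)
        pq = simulate.sample_pq(plot, seed=seed + 1)
        bundle = {"points": pd.concat([cpi, pq], ignore_index=True),
                  "realized_fractions": plot.realized_fractions,
                  "design": simulate.design_summary(
                      spec, float(np.mean(simulate.chain_lengths(plot))))}
    else:
        raise ValueError("kind must be 'site' or 'plot'")
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv", index=False)
        side = {"seed": seed, "kind": kind,
                "spec": repr(spec)}
        (out / "metadata.json").write_text(json.dumps(side, indent=2))
    return bundle


def PlotDefaults() -> simulate.PlotSimSpec:
    """Default mechanistic plot: rugose corals/sponges, inflated
    gorgonians, flat algal components."""
    H = simulate.ComponentHabit
    return simulate.PlotSimSpec(components={
        "hard_corals": H(0.20, rugosity=1.8),
        "sponges": H(0.05, rugosity=1.6),
        "gorgonians": H(0.08, rugosity=1.0, inflation=2.0),
        "macroalgae": H(0.15, rugosity=1.2),
        "turf_algae": H(0.30, rugosity=1.1),
        "cca": H(0.07, rugosity=1.1),
        "other": H(0.15, rugosity=1.2),
    })


def run_temporal(baseline: pd.DataFrame, current: pd.DataFrame,
                 component: str = "hard_corals", rules=None,
                 min_sites: int = 5) -> dict:
    """Per-site change between two survey epochs, three ways.

    ``baseline`` is a cover table of the reference method (CPI) at the
    earlier epoch; ``current`` a cover table carrying one or both methods
    at the later epoch.  Changes (current - baseline) are tested with a
    signed-rank test pooled across reef types, for every available
    comparison: current CPI vs baseline, current raw PQ vs baseline and,
    when ``rules`` are supplied, current converted PQ vs baseline —
    demonstrating how an unconverted method switch can reverse an
    apparent trend.
    """
    base = baseline[(baseline["component"] == component)
                    & (baseline["method"] == "CPI")]
    base = base.set_index("site_id")["cover"]
    cur = current[current["component"] == component]
    out: dict = {"component": component, "comparisons": {}}
    unmatched = sorted(set(cur["site_id"]) ^ set(base.index))
    out["unmatched_sites"] = unmatched
    matched = sorted(set(cur["site_id"]) & set(base.index))
    if len(matched) < min_sites:
        import warnings
        warnings.warn(f"only {len(matched)} matched sites", stacklevel=2)

    def _one(label: str, values: pd.Series):
        common = values.index.intersection(base.index)
        deltas = (values.loc[common] - base.loc[common]).to_numpy()
        entry = {
            "n": int(deltas.size),
            "median_change": float(np.median(deltas)),
            "mean_change": float(np.mean(deltas)),
        }
        try:
            entry.update(agreement.signed_rank_test(deltas))
        except ValueError as exc:  # all-zero changes: degenerate but valid
            entry["degenerate"] = str(exc)
        out["comparisons"][label] = entry

    for method in ("CPI", "PQ"):
        sub = cur[cur["method"] == method]
        if len(sub):
            _one(f"{method.lower()}_vs_baseline",
                 sub.set_index("site_id")["cover"])
    if rules is not None:
        sub = cur[cur["method"] == "PQ"]
        if len(sub):
            conv = apply_rules(rules, sub)
            _one("converted_pq_vs_baseline",
                 conv.set_index("site_id")["converted"])
    return out
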