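"""Heteroscedastic GLS ANCOVA: estimation, F-tests, reduction, diagnostics."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import reefcal as rc
from reefcal.ancova import (DegenerateVarianceError, DifferenceGLS,
                            ScenarioClass, classify_scenario, fit_gls,
                            reduce_model, residual_diagnostics)


def _toy(seed=0, n=60, betas=(1.0, -2.0, 0.5), deltas=(1.0, 1.0, 1.0),
         sigma=1.0):
    """Three balanced groups, known coefficients per group structure."""
    rng = np.random.default_rng(seed)
    reef = np.repeat(["bank", "fringing", "patch"], n // 3)
    a = rng.uniform(5, 40, size=n)
    b0 = dict(zip(["bank", "fringing", "patch"], betas))
    sd = dict(zip(["bank", "fringing", "patch"], deltas))
    d = np.array([b0[r] for r in reef]) + 0.1 * a \
        + rng.normal(0, sigma, n) * np.array([sd[r] for r in reef])
    return pd.DataFrame({"reef_type": reef, "a": a, "d": d})


class TestEstimation:
    def test_gls_equals_ols_with_unit_weights(self):
        """Constraining every variance multiplier to 1 is exactly OLS."""
        df = _toy(seed=1)
        res = fit_gls(df, fixed_delta={"bank": 1.0, "fringing": 1.0,
                                       "patch": 1.0})
        m = DifferenceGLS.from_dataframe(df)
        X, _, _ = m._design(m.terms)
        beta_ols, *_ = np.linalg.lstsq(X, df["d"].to_numpy(), rcond=None)
        np.testing.assert_allclose(res.params.to_numpy(), beta_ols,
                                   atol=1e-10)

    def test_homoscedastic_fit_matches_ols_too(self):
        df = _toy(seed=2)
        res = fit_gls(df, variance_groups=False)
        assert set(res.delta.values()) == {1.0}
        res_fixed = fit_gls(df, fixed_delta={"bank": 1.0, "fringing": 1.0,
                                             "patch": 1.0})
        np.testing.assert_allclose(res.params.to_numpy(),
                                   res_fixed.params.to_numpy(), atol=1e-12)

    def test_known_weights_match_closed_form(self):
        """Weighted normal equations oracle at fixed delta."""
        rng = np.random.default_rng(5)
        reef = np.repeat(["bank", "patch"], 8)
        a = rng.uniform(0, 30, 16)
        d = 2.0 - 0.3 * a + rng.normal(0, 1, 16)
        df = pd.DataFrame({"reef_type": reef, "a": a, "d": d})
        delta = {"bank": 1.0, "patch": 2.0}
        res = fit_gls(df, terms=("factor", "covariate"), fixed_delta=delta)
        m = DifferenceGLS.from_dataframe(df, terms=("factor", "covariate"))
        X, _, _ = m._design(m.terms)
        w = np.where(reef == "bank", 1.0, 1.0 / 4.0)  # 1/delta^2
        XtWX = X.T @ (w[:, None] * X)
        XtWy = X.T @ (w * d)
        beta = np.linalg.solve(XtWX, XtWy)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)

    def test_reml_estimates_variance_ratio(self):
        """With a true 3x SD group the multiplier is recovered (large n)."""
        df = _toy(seed=3, n=600, deltas=(1.0, 3.0, 1.0))
        res = fit_gls(df)
        assert res.converged
        assert res.delta["fringing"] == pytest.approx(3.0, rel=0.25)
        assert res.delta["patch"] == pytest.approx(1.0, rel=0.25)
        assert res.sigma > 0

    def test_shift_equivariance(self):
        """Adding k to every d shifts intercepts by k, nothing else."""
        df = _toy(seed=4)
        res = fit_gls(df)
        shifted = df.assign(d=df["d"] + 7.5)
        res2 = fit_gls(shifted)
        assert res2.params["Intercept"] == pytest.approx(
            res.params["Intercept"] + 7.5, abs=1e-6)
        for name in res.params.index:
            if name != "Intercept":
                assert res2.params[name] == pytest.approx(
                    res.params[name], abs=1e-6)
        for k in res.delta:
            assert res2.delta[k] == pytest.approx(res.delta[k], abs=1e-5)
        t1, t2 = res.anova(), res2.anova()
        np.testing.assert_allclose(t1["F"].iloc[1:], t2["F"].iloc[1:],
                                   rtol=1e-5)

    def test_singular_design_raises(self):
        df = pd.DataFrame({
            "reef_type": ["bank", "bank", "bank", "patch"],
            "a": [1.0, 2.0, 3.0, 4.0],
            "d": [0.1, 0.2, 0.3, 0.4],
        })
        with pytest.raises(ValueError):
            # patch has one site: no free variance multiplier, and the
            # interaction column is collinear with its dummy
            DifferenceGLS.from_dataframe(df)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"reef_type": ["bank"] * 4 + ["patch"] * 4,
                           "a": [5.0] * 8,
                           "d": [1.0, 2.0, 1.5, 2.5, 0.5, 1.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_gls(df)


class TestAgainstNlme:
    def test_matches_r_reference(self, hard_coral_diffs, tmp_path):
        """Coefficients, scale, variance multipliers and the sequential
        F-table agree with R's nlme gls + varIdent on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; reference check cannot run")
        data = tmp_path / "d.csv"
        hard_coral_diffs[["reef_type", "d", "a"]].to_csv(data, index=False)
        script = tmp_path / "fit.R"
        script.write_text("""
suppressMessages({library(nlme); library(jsonlite)})
d <- read.csv(commandArgs(TRUE)[1]); d$reef_type <- factor(d$reef_type)
m <- gls(d ~ reef_type * a, data = d,
         weights = varIdent(form = ~1 | reef_type), method = "REML")
a <- anova(m)
cat(toJSON(list(coef = as.numeric(coef(m)), sigma = summary(m)$sigma,
  delta = as.numeric(coef(m$modelStruct$varStruct, unconstrained = FALSE)),
  F = as.numeric(a[["F-value"]]), p = as.numeric(a[["p-value"]])),
  digits = 12))
""")
        out = subprocess.run(["Rscript", str(script), str(data)],
                             capture_output=True, text=True, check=True)
        ref = json.loads(out.stdout)
        res = fit_gls(hard_coral_diffs)
        np.testing.assert_allclose(res.params.to_numpy(), ref["coef"],
                                   rtol=1e-5)
        assert res.sigma == pytest.approx(ref["sigma"][0], rel=1e-5)
        levels = res.model.levels[1:]
        np.testing.assert_allclose([res.delta[l] for l in levels],
                                   ref["delta"], rtol=1e-4)
        tab = res.anova()
        np.testing.assert_allclose(tab["F"].to_numpy(), ref["F"], rtol=1e-5)
        np.testing.assert_allclose(tab["p"].to_numpy(), ref["p"],
                                   atol=1e-6)


class TestSequentialF:
    def test_full_model_df_pattern(self, hard_coral_diffs):
        """n=21 with 6 parameters puts 15 denominator df on every row."""
        tab = fit_gls(hard_coral_diffs).anova()
        assert list(tab["df_den"]) == [15] * 4
        assert list(tab["df_num"]) == [1, 2, 1, 2]
        assert list(tab["term"]) == ["Intercept", "Reef type",
                                     "Average cover",
                                     "Reef type x Average cover"]

    def test_zero_residual_raises_degenerate(self):
        df = pd.DataFrame({"reef_type": ["bank"] * 5 + ["patch"] * 5,
                           "a": np.arange(10.0),
                           "d": 2.0 + 0.5 * np.arange(10.0)})
        res = fit_gls(df, terms=("factor", "covariate"),
                      variance_groups=False)
        assert res.sigma == 0.0
        with pytest.raises(DegenerateVarianceError):
            res.anova()

    def test_reordering_preserves_last_term(self, hard_coral_diffs):
        """The last term's sequential F is order-invariant (it is the
        marginal test given everything else)."""
        res = fit_gls(hard_coral_diffs, terms=("factor", "covariate"))
        t1 = res.anova(term_order=("factor", "covariate"))
        t2 = res.anova(term_order=("covariate", "factor"))
        assert t1.iloc[-1]["term"] == "Average cover"
        assert t2.iloc[-1]["term"] == "Reef type"
        # total explained SS is invariant to ordering
        assert t1["F"].iloc[1:] @ t1["df_num"].iloc[1:] == pytest.approx(
            t2["F"].iloc[1:] @ t2["df_num"].iloc[1:], rel=1e-9)


class TestReductionAndClassification:
    def _classify_seeds(self, class_name, n, sigma=0.75, start=40):
        from reefcal.validation import component_diffs
        spec = rc.simulate.scenario_exemplars(sigma=sigma)[class_name]
        comp = next(iter(spec.components))
        got = []
        seed = start
        while len(got) < n:
            seed += 1
            try:
                diffs = component_diffs(spec, seed, comp)
            except ValueError:
                continue  # unrealizable draw under the clamp guard
            reduced, _ = reduce_model(diffs)
            got.append(classify_scenario(reduced).value)
        return got

    @pytest.mark.parametrize("class_name", [
        "CONSTANT_POOLED", "CONSTANT_BY_REEF",
        "COMMON_SLOPE_BY_REEF", "SLOPE_BY_REEF",
    ])
    def test_exemplar_recovery_majority(self, class_name):
        """Each scenario exemplar is recovered in most replicates (the
        per-test false-positive rates bound this well below 1)."""
        got = self._classify_seeds(class_name, n=9)
        assert got.count(class_name) >= 5, got

    def test_trace_is_recorded(self, hard_coral_diffs):
        reduced, trace = reduce_model(hard_coral_diffs)
        assert len(trace) >= 1
        assert all({"terms", "tested", "dropped"} <= set(t) for t in trace)
        dropped = [t["dropped"] for t in trace if t["dropped"]]
        assert "interaction" not in reduced.model.terms or not dropped

    def test_marginality_respected(self, hard_coral_diffs):
        """Main effects are never tested while the interaction stands."""
        _, trace = reduce_model(hard_coral_diffs)
        for step in trace:
            if "interaction" in step["terms"]:
                assert set(step["tested"]) == {"interaction"}

    def test_no_difference_when_truly_null(self):
        """With no bias at all the chain usually ends at NO_DIFFERENCE
        (the stepwise chain's compounded false-positive rate caps this
        near 70% at this design size)."""
        spec = rc.simulate.SiteSimSpec(components={
            "coral": rc.simulate.ComponentScenario(cover=(20, 5),
                                                   sigma=1.0)})
        from reefcal.validation import component_diffs
        hits = 0
        for s in range(20):
            reduced, _ = reduce_model(component_diffs(spec, s, "coral"))
            hits += classify_scenario(reduced) is ScenarioClass.NO_DIFFERENCE
        assert hits >= 10

    def test_intercept_only_recovers_pooled_offset(self):
        """A pure constant offset is estimated near truth whenever the
        chain retains only the intercept."""
        spec = rc.simulate.SiteSimSpec(components={
            "sponge": rc.simulate.ComponentScenario(cover=(9, 2),
                                                    beta0=-3.9,
                                                    sigma=0.75)})
        from reefcal.validation import component_diffs
        classes, intercepts = [], []
        for s in range(41, 53):
            reduced, _ = reduce_model(component_diffs(spec, s, "sponge"))
            cls = classify_scenario(reduced)
            classes.append(cls)
            if cls is ScenarioClass.CONSTANT_POOLED:
                intercepts.append(float(reduced.params["Intercept"]))
        assert classes.count(ScenarioClass.CONSTANT_POOLED) >= 6
        assert np.mean(intercepts) == pytest.approx(-3.9, abs=0.6)


class TestDiagnostics:
    def test_adequate_variance_model(self):
        df = _toy(seed=8, n=21)
        rep = residual_diagnostics(fit_gls(df))
        assert set(rep["group_sd"]) == {"bank", "fringing", "patch"}
        assert all(0.3 < v < 1.7 for v in rep["group_sd"].values())

    def test_ignored_heteroscedasticity_flagged(self):
        df = _toy(seed=9, n=120, deltas=(1.0, 4.0, 1.0))
        rep = residual_diagnostics(fit_gls(df, variance_groups=False))
        assert rep["heterogeneity_ratio"] > 2.0
        assert "fringing" in rep["flagged"]

    def test_zero_residual_degenerate_report(self):
        df = pd.DataFrame({"reef_type": ["bank"] * 5 + ["patch"] * 5,
                           "a": np.arange(10.0),
                           "d": 1.0 + 0.2 * np.arange(10.0)})
        res = fit_gls(df, terms=("factor", "covariate"),
                      variance_groups=False)
        rep = residual_diagnostics(res)
        assert rep["degenerate"]
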