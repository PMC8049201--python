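import numpy as np
import pandas as pd
import pytest

from gpcomplexity import reference
from gpcomplexity.codesets import CodeSetRegistry, FactorDefinition
from gpcomplexity.develop import (
    ModelFit,
    PipelineConfig,
    assemble_measure,
    backward_stepwise,
    fit_duration_model,
    prevalence_screen,
    reclassify_low_prevalence,
    specify_percentile_threshold,
)
from gpcomplexity.factors import compute_flags
from gpcomplexity.synthetic import SimulationConfig, simulate_dataset


def _flags_and_consultations(n, true_ids, factor="f", patient_per_consult=True):
    flags = pd.DataFrame(
        {factor: [i in set(true_ids) for i in range(1, n + 1)]},
        index=pd.Index(range(1, n + 1), name="consultation_id"),
    )
    cons = pd.DataFrame(
        {
            "consultation_id": range(1, n + 1),
            "patient_id": range(1, n + 1) if patient_per_consult else [1] * n,
            "date": pd.Timestamp("2014-01-01"),
            "duration_minutes": 10.0,
        }
    )
    return flags, cons


def _registry_one(level="consultation"):
    kwargs = {"lookback_days": 365} if level == "patient" else {}
    return CodeSetRegistry(
        [FactorDefinition("f", "f", level, "code_match", frozenset({"X1"}), **kwargs)]
    )


class TestPrevalenceScreen:
    def test_below_threshold_excluded(self):
        flags, cons = _flags_and_consultations(10_000, [1, 2])
        out = prevalence_screen(flags, _registry_one(), cons).iloc[0]
        assert out["prevalence"] == pytest.approx(0.0002)
        assert out["excluded"]

    def test_exactly_at_threshold_retained(self):
        flags, cons = _flags_and_consultations(10_000, [1, 2, 3, 4, 5])
        out = prevalence_screen(flags, _registry_one(), cons).iloc[0]
        assert out["prevalence"] == pytest.approx(0.0005)
        assert not out["excluded"]  # strict < comparison

    def test_patient_factor_uses_patient_denominator(self):
        # 4 consultations of one flagged patient: patient prevalence 1/3
        flags = pd.DataFrame(
            {"f": [True, True, True, True, False, False]},
            index=pd.Index(range(1, 7), name="consultation_id"),
        )
        cons = pd.DataFrame(
            {
                "consultation_id": range(1, 7),
                "patient_id": [1, 1, 1, 1, 2, 3],
                "date": pd.Timestamp("2014-01-01"),
                "duration_minutes": 10.0,
            }
        )
        out = prevalence_screen(flags, _registry_one("patient"), cons).iloc[0]
        assert out["numerator"] == 1 and out["denominator"] == 3
        assert out["prevalence"] == pytest.approx(1 / 3)

    def test_scale_invariance_under_duplication(self):
        flags, cons = _flags_and_consultations(2_000, [1])
        first = prevalence_screen(flags, _registry_one(), cons)
        dup_flags = pd.concat(
            [flags, flags.set_axis(flags.index + 2_000)]
        )
        dup_cons = pd.concat(
            [cons, cons.assign(consultation_id=cons["consultation_id"] + 2_000)]
        )
        second = prevalence_screen(dup_flags, _registry_one(), dup_cons)
        assert first["excluded"].equals(second["excluded"])
        assert first["prevalence"].equals(second["prevalence"])

    def test_planted_prevalence_exclusion_oracle(self, small_dataset, toy_registry):
        """Exclusion decisions equal a brute-force recount of planted flags."""
        truth = small_dataset.truth_flags
        ids = sorted(small_dataset.truth.factor_prevalence)
        config = PipelineConfig(exclusion_threshold=0.02)
        out = prevalence_screen(
            truth, toy_registry.subset(ids), small_dataset.consultations, config
        ).set_index("factor_id")
        for f in ids:
            brute = truth[f].mean()
            assert out.loc[f, "excluded"] == (brute < 0.02)

    def test_zero_denominator_errors(self):
        flags, cons = _flags_and_consultations(0, [])
        with pytest.raises(ValueError, match="denominator|no flagged"):
            prevalence_screen(flags, _registry_one(), cons)


class TestPercentileThreshold:
    def test_constant_distribution(self):
        assert specify_percentile_threshold([3] * 50, 0.95) == 3

    def test_uniform_1_to_100_sort_oracle(self):
        counts = np.arange(1, 101)
        # brute force: smallest value whose empirical CDF reaches 0.95
        srt = np.sort(counts)
        cdf = np.arange(1, 101) / 100
        brute = srt[np.argmax(cdf >= 0.95)]
        assert specify_percentile_threshold(counts, 0.95) == brute == 95

    def test_engineered_95th_centile_of_14(self):
        counts = np.array([3] * 94 + [14, 15, 16, 17, 18, 19])
        assert specify_percentile_threshold(counts, 0.95) == 14

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            specify_percentile_threshold([])


class TestReclassification:
    def test_empty_map_is_identity(self, toy_registry):
        assert reclassify_low_prevalence(toy_registry, {}) == toy_registry

    def test_published_map_yields_11_consultation_factors(self, toy_registry):
        endorsed = reference.replay_delphi()
        endorsed = endorsed[endorsed["final_status"] == "endorsed"]
        cons_ids = endorsed.loc[endorsed["level"] == "consultation", "factor_id"]
        pat_ids = endorsed.loc[endorsed["level"] == "patient", "factor_id"]
        keep = [
            f
            for f in list(cons_ids) + list(pat_ids)
            if f not in reference.LOW_PREVALENCE_EXCLUSIONS
        ]
        registry = toy_registry.subset(keep)
        updated = reclassify_low_prevalence(
            registry, reference.reclassification_map(toy_registry)
        )
        assert len(updated.factor_ids("consultation")) == 11
        assert len(updated.factor_ids("patient")) == 15

    def test_unknown_factor_errors(self, toy_registry):
        target = toy_registry["homelessness_patient"]
        with pytest.raises(ValueError, match="unknown factor"):
            reclassify_low_prevalence(toy_registry, {"ghost": target})

    def test_conflicting_window_errors(self, toy_registry):
        conflicting = FactorDefinition(
            "homelessness_patient",
            "conflict",
            "patient",
            "code_match",
            frozenset({"HMP1."}),
            lookback_days=9999,
        )
        with pytest.raises(ValueError, match="conflicting window"):
            reclassify_low_prevalence(
                toy_registry, {"homeless_presenting": conflicting}
            )


def _sim_for_modelling(seed, effects, prevalences, n_practices=10,
                       patients=40, rate=8.0, sds=(0.3, 0.5, 2.0)):
    cfg = SimulationConfig(
        n_practices=n_practices,
        patients_per_practice=patients,
        consult_rate_per_year=rate,
        factor_prevalence=prevalences,
        duration_baseline_minutes=9.78,
        factor_effects_minutes=effects,
        sd_practice=sds[0],
        sd_patient=sds[1],
        sd_residual=sds[2],
        study_window=("2013-04-01", "2014-04-01"),
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    reg = reference.toy_registry().subset(sorted(prevalences))
    flags = compute_flags(reg, ds.consultations, ds.events, ds.prescriptions)
    return ds, flags


THREE_FACTORS = ["mental_health_consult", "dementia_consult", "chronic_pain_consult"]


class TestFitDurationModel:
    def test_zero_variance_matches_ols_oracle(self):
        import statsmodels.api as sm

        ds, flags = _sim_for_modelling(
            0,
            {f: e for f, e in zip(THREE_FACTORS, (3.85, 1.42, 0.98))},
            {f: 0.2 for f in THREE_FACTORS},
            sds=(0.0, 0.0, 2.0),
        )
        fit = fit_duration_model(
            ds.patients, ds.consultations, flags, THREE_FACTORS, fix_gamma=(0.0, 0.0)
        )
        X = np.column_stack(
            [np.ones(len(flags))] + [flags[f].to_numpy(float) for f in THREE_FACTORS]
        )
        ols = sm.OLS(ds.consultations["duration_minutes"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.intercept[0], ols.params[0], rtol=1e-10)
        np.testing.assert_allclose(
            fit.terms["estimate_minutes"].to_numpy(), ols.params[1:], rtol=1e-10
        )

    def test_univariable_mode_fits_one_factor_at_a_time(self):
        ds, flags = _sim_for_modelling(
            1,
            {f: e for f, e in zip(THREE_FACTORS, (3.85, 1.42, 0.98))},
            {f: 0.2 for f in THREE_FACTORS},
        )
        uni = fit_duration_model(
            ds.patients, ds.consultations, flags, THREE_FACTORS, mode="univariable"
        )
        assert uni.intercept is None
        assert list(uni.terms["factor_id"]) == THREE_FACTORS
        solo = fit_duration_model(
            ds.patients, ds.consultations, flags, [THREE_FACTORS[0]]
        )
        assert uni.terms.iloc[0]["estimate_minutes"] == pytest.approx(
            solo.terms.iloc[0]["estimate_minutes"]
        )

    def test_constant_factor_is_singular(self):
        ds, flags = _sim_for_modelling(
            2, {}, {"mental_health_consult": 0.2}
        )
        flags["always"] = True
        with pytest.raises(ValueError, match="singular|constant"):
            fit_duration_model(ds.patients, ds.consultations, flags, ["always"])

    def test_needs_two_practices(self):
        ds, flags = _sim_for_modelling(
            3, {}, {"mental_health_consult": 0.3}, n_practices=1
        )
        with pytest.raises(ValueError, match="two practices"):
            fit_duration_model(
                ds.patients, ds.consultations, flags, ["mental_health_consult"]
            )

    def test_model_fit_invariants(self):
        ds, flags = _sim_for_modelling(
            4, {"mental_health_consult": 3.85}, {"mental_health_consult": 0.3}
        )
        fit = fit_duration_model(
            ds.patients, ds.consultations, flags, ["mental_health_consult"]
        )
        t = fit.terms.iloc[0]
        assert t["ci_low"] <= t["estimate_minutes"] <= t["ci_high"]
        assert all(v >= 0 for v in fit.variance_components.values())
        assert fit.n_consultations == len(flags)


class TestBackwardStepwise:
    def test_all_significant_is_fixed_point(self):
        ds, flags = _sim_for_modelling(
            5,
            {f: e for f, e in zip(THREE_FACTORS, (4.0, 3.0, 2.0))},
            {f: 0.25 for f in THREE_FACTORS},
        )
        fit, log = backward_stepwise(
            ds.patients, ds.consultations, flags, THREE_FACTORS
        )
        assert log.empty
        assert sorted(fit.factor_ids) == sorted(THREE_FACTORS)

    def test_null_factor_removed_in_most_replicates(self):
        """One true-zero factor among strong positives is the factor
        removed in >=90% of 20 seeded replicates."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            ds, flags = _sim_for_modelling(
                1000 + seed,
                {"mental_health_consult": 4.0, "dementia_consult": 3.0,
                 "chronic_pain_consult": 0.0},
                {f: 0.25 for f in THREE_FACTORS},
            )
            fit, log = backward_stepwise(
                ds.patients, ds.consultations, flags, THREE_FACTORS
            )
            removed = set(log["factor_id"])
            if removed == {"chronic_pain_consult"}:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_negative_factor_removed_first_in_one_pass(self):
        ds, flags = _sim_for_modelling(
            6,
            {"mental_health_consult": 4.0, "dementia_consult": -2.0},
            {"mental_health_consult": 0.25, "dementia_consult": 0.25},
        )
        fit, log = backward_stepwise(
            ds.patients, ds.consultations, flags,
            ["mental_health_consult", "dementia_consult"],
        )
        neg = log[log["reason"] == "negative_coefficient"]
        assert list(neg["factor_id"]) == ["dementia_consult"]
        assert (neg["step"] == 0).all()
        assert fit.factor_ids == ["mental_health_consult"]

    def test_terminates_and_strictly_shrinks(self):
        ds, flags = _sim_for_modelling(
            7,
            {f: 0.0 for f in THREE_FACTORS},
            {f: 0.25 for f in THREE_FACTORS},
        )
        with pytest.warns(RuntimeWarning, match="every factor"):
            fit, log = backward_stepwise(
                ds.patients, ds.consultations, flags, THREE_FACTORS
            )
        assert len(log) <= len(THREE_FACTORS)
        assert log["factor_id"].is_unique
        assert fit.terms.empty and fit.intercept is not None
        assert fit.intercept[0] == pytest.approx(9.78, abs=0.5)


class TestAssembleMeasure:
    def _fit(self, ids):
        return ModelFit(
            mode="multivariable",
            terms=pd.DataFrame(
                {"factor_id": ids, "estimate_minutes": 1.0, "ci_low": 0.5,
                 "ci_high": 1.5, "p_value": 0.001}
            ),
            intercept=(9.78, 9.5, 10.0, 0.001),
            variance_components={},
            n_consultations=0,
            n_patients=0,
            n_practices=0,
            loglik=None,
            converged=True,
        )

    def test_union_with_provenance(self):
        out = assemble_measure(self._fit(["a", "b"]), self._fit(["c"]))
        assert list(out["factor_id"]) == ["a", "b", "c"]
        assert set(out["source"]) == {"consultation_model", "patient_model"}

    def test_override_only_path(self):
        out = assemble_measure(None, None, overrides=["x", "y"])
        assert list(out["factor_id"]) == ["x", "y"]
        assert (out["source"] == "override").all()

    def test_duplicate_across_fits_errors(self):
        with pytest.raises(ValueError, match="disjoint"):
            assemble_measure(self._fit(["a"]), self._fit(["a"]))

    def test_unknown_override_errors(self, toy_registry):
        with pytest.raises(ValueError, match="unknown factor"):
            assemble_measure(None, None, overrides=["ghost"], registry=toy_registry)

    def test_published_overrides_resolve(self, toy_registry):
        out = assemble_measure(
            None, None, overrides=reference.VALIDATION_OVERRIDES, registry=toy_registry
        )
        assert len(out) == 5


def test_pipeline_config_bounds():
    with pytest.raises(ValueError, match="exclusion_threshold"):
        PipelineConfig(exclusion_threshold=0.0)
    with pytest.raises(ValueError, match="stepwise_alpha"):
        PipelineConfig(stepwise_alpha=1.5)
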