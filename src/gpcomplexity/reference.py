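"""Bundled reference data for the released consultation-complexity measure.

This module encodes, as plain data, the published bookkeeping behind the
17-factor measure: the 45 candidate factors tracked across the two
consensus rounds with their per-round statuses, the development-year
regression table used for the sign/significance bookkeeping, the final
effect estimates, and a toy code-set registry that expresses every factor
rule in the shipped file format (the real clinical code sets are licensed
and deposited elsewhere; the toy codes are placeholders with the same
structure).

It also provides replay helpers that push the recorded statuses through
the actual workflow implementations, and a ready-made simulation
configuration whose ground-truth effects are the published final-model
coefficients.
"""

from __future__ import annotations

import pandas as pd

from .codesets import CodeSetRegistry, FactorDefinition
from .delphi import DelphiThresholds, run_two_rounds, votes_for_outcome
from .synthetic import SimulationConfig

__all__ = [
    "delphi_outcomes",
    "build_replay_votes",
    "replay_delphi",
    "LOW_PREVALENCE_EXCLUSIONS",
    "RECLASSIFIED_TO_PATIENT",
    "VALIDATION_OVERRIDES",
    "initial_model_2013",
    "final_effects_2013",
    "replay_measure_selection",
    "toy_registry",
    "reclassification_map",
    "reference_simulation_config",
]

# ---------------------------------------------------------------------------
# Candidate factors and two-round consensus statuses
# ---------------------------------------------------------------------------
# (factor_id, level, round-1 status, round-2 status); None = not voted on
# in that round. Factors with no round-1 status were suggested by
# panelists between rounds and first voted on in round 2.

_E, _R, _U = "endorsed", "rejected", "uncertain"

_DELPHI_ROWS = [
    # consultation factors, initial round-1 set (14)
    ("homeless_presenting", "consultation", _E, None),
    ("safeguarding_concern", "consultation", _E, None),
    ("domestic_violence_concern", "consultation", _E, None),
    ("learning_disability_consult", "consultation", _E, None),
    ("end_of_life_discussion", "consultation", _E, None),
    ("mental_health_consult", "consultation", _E, None),
    ("multiple_diagnoses", "consultation", _E, None),
    ("dementia_consult", "consultation", _U, _E),
    ("drug_alcohol_consult", "consultation", _U, _E),
    ("preventive_tasks", "consultation", _U, _E),
    ("minor_surgery", "consultation", _U, _U),
    ("many_drugs_prescribed", "consultation", _U, _E),
    ("first_consult_cancer", "consultation", _U, _E),
    ("first_consult_diabetes", "consultation", _U, _E),
    # consultation factors suggested between rounds (5)
    ("mus_consult", "consultation", None, _E),
    ("outpatient_referral_result", "consultation", None, _R),
    ("emergency_admission", "consultation", None, _E),
    ("urgent_secondary_care", "consultation", None, _E),
    ("chronic_pain_consult", "consultation", None, _E),
    # patient factors, initial round-1 set (19)
    ("homelessness_patient", "patient", _E, None),
    ("safeguarding_patient", "patient", _E, None),
    ("domestic_violence_patient", "patient", _E, None),
    ("interpreter_needed", "patient", _E, None),
    ("learning_disability_patient", "patient", _E, None),
    ("dementia_patient", "patient", _E, None),
    ("palliative_care_patient", "patient", _E, None),
    ("drug_alcohol_patient", "patient", _E, None),
    ("severe_mental_illness", "patient", _E, None),
    ("wheelchair_use", "patient", _R, None),
    ("recent_outpatient_referral", "patient", _R, None),
    ("warfarin_use", "patient", _R, None),
    ("cancer_ever", "patient", _R, None),
    ("diabetes_ever", "patient", _R, None),
    ("ltc_3plus", "patient", _U, _E),
    ("deafness", "patient", _U, _U),
    ("paraplegia", "patient", _U, _E),
    ("blind_partial_sight", "patient", _U, _U),
    ("immunosuppressant", "patient", _U, _U),
    # patient factors suggested between rounds (7)
    ("housebound_nursing_home", "patient", None, _E),
    ("personality_disorder", "patient", None, _E),
    ("mus_patient", "patient", None, _E),
    ("morbid_obesity", "patient", None, _U),
    ("frequent_attender", "patient", None, _E),
    ("chronic_pain_patient", "patient", None, _E),
    ("polypharmacy", "patient", None, _E),
]


def delphi_outcomes() -> pd.DataFrame:
    """All 45 candidate factors with their recorded per-round statuses."""
    return pd.DataFrame(
        _DELPHI_ROWS, columns=["factor_id", "level", "round1_status", "round2_status"]
    )


def build_replay_votes(
    n_round1: int = 32, n_round2: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Deterministic vote tables reproducing the recorded statuses.

    Returns (round-1 votes, round-2 votes, round-2 new factor ids); the
    panel sizes default to the recorded participation (32 in round 1, 30
    in round 2).
    """
    outcomes = delphi_outcomes()
    r1_frames, r2_frames, new_factors = [], [], []
    for row in outcomes.itertuples(index=False):
        if row.round1_status is not None:
            r1_frames.append(
                votes_for_outcome(row.round1_status, n_round1, row.factor_id, round=1)
            )
        else:
            new_factors.append(row.factor_id)
        if row.round2_status is not None:
            r2_frames.append(
                votes_for_outcome(row.round2_status, n_round2, row.factor_id, round=2)
            )
    return (
        pd.concat(r1_frames, ignore_index=True),
        pd.concat(r2_frames, ignore_index=True),
        new_factors,
    )


def replay_delphi(thresholds: DelphiThresholds | None = None) -> pd.DataFrame:
    """Run the two-round workflow on the recorded statuses.

    Reconstructs vote tables that classify exactly as recorded, pushes
    them through :func:`gpcomplexity.delphi.run_two_rounds`, and returns
    the final status table joined with each factor's level.
    """
    r1, r2, new = build_replay_votes()
    final = run_two_rounds(r1, r2, new, thresholds)
    return final.merge(delphi_outcomes()[["factor_id", "level"]], on="factor_id")


# ---------------------------------------------------------------------------
# Development-pipeline bookkeeping
# ---------------------------------------------------------------------------

#: Endorsed factors dropped for prevalence < 0.05% of consultations/patients.
LOW_PREVALENCE_EXCLUSIONS = (
    "mus_consult",
    "urgent_secondary_care",
    "paraplegia",
    "mus_patient",
)

#: Endorsed consultation factors excluded at consultation level but carried
#: into the modelling as (pre-existing) patient-level factors.
RECLASSIFIED_TO_PATIENT = {
    "end_of_life_discussion": "palliative_care_patient",
    "homeless_presenting": "homelessness_patient",
    "domestic_violence_concern": "domestic_violence_patient",
    "safeguarding_concern": "safeguarding_patient",
}

#: Factors kept in the released measure despite low prevalence or lack of
#: significance in the later validation year.
VALIDATION_OVERRIDES = (
    "dementia_consult",
    "drug_alcohol_patient",
    "homelessness_patient",
    "ltc_3plus",
    "personality_disorder",
)

# Development-year initial regressions. Estimates in minutes; p-values
# reported as "<0.001" are encoded as 1e-4; a missing multivariable entry
# (None) marks a factor excluded for its negative duration relationship.
_INITIAL_MODEL_ROWS = [
    # level, factor_id, uni(est, lo, hi, p), multi(est, lo, hi, p)
    ("consultation", "drug_alcohol_consult", (4.49, 3.99, 4.98, 1e-4), (4.19, 3.68, 4.69, 1e-4)),
    ("consultation", "chronic_pain_consult", (1.48, 1.37, 1.60, 1e-4), (0.98, 0.86, 1.10, 1e-4)),
    ("consultation", "dementia_consult", (1.45, 0.92, 1.98, 1e-4), (1.42, 0.90, 1.94, 1e-4)),
    ("consultation", "emergency_admission", (7.81, 7.12, 8.50, 1e-4), (7.76, 7.09, 8.43, 1e-4)),
    ("consultation", "learning_disability_consult", (4.54, 3.86, 5.22, 1e-4), (3.84, 3.17, 4.52, 1e-4)),
    ("consultation", "mental_health_consult", (4.06, 3.92, 4.21, 1e-4), (3.85, 3.70, 3.99, 1e-4)),
    ("consultation", "multiple_diagnoses", (2.99, 2.87, 3.12, 1e-4), (2.54, 2.42, 2.67, 1e-4)),
    ("consultation", "many_drugs_prescribed", (1.93, 1.87, 1.99, 1e-4), (1.73, 1.67, 1.80, 1e-4)),
    ("consultation", "preventive_tasks", (3.94, 3.75, 4.13, 1e-4), (3.73, 3.55, 3.92, 1e-4)),
    ("consultation", "first_consult_cancer", (0.59, 0.04, 1.14, 0.037), (0.43, -0.11, 0.97, 0.118)),
    ("consultation", "first_consult_diabetes", (3.59, 3.00, 4.17, 1e-4), (3.05, 2.48, 3.63, 1e-4)),
    ("patient", "drug_alcohol_patient", (2.03, 1.58, 2.48, 1e-4), (1.89, 1.44, 2.33, 1e-4)),
    ("patient", "chronic_pain_patient", (0.87, 0.72, 1.02, 1e-4), (0.73, 0.58, 0.89, 1e-4)),
    ("patient", "dementia_patient", (-0.78, -1.19, -0.38, 1e-4), None),
    ("patient", "domestic_violence_patient", (1.46, 0.40, 2.52, 0.007), (1.43, 0.37, 2.49, 0.008)),
    ("patient", "frequent_attender", (0.35, 0.19, 0.52, 1e-4), (0.01, -0.17, 0.19, 0.902)),
    ("patient", "homelessness_patient", (1.64, 0.67, 2.61, 1e-4), (1.36, 0.39, 2.33, 0.006)),
    ("patient", "housebound_nursing_home", (-3.72, -4.37, -3.06, 1e-4), None),
    ("patient", "interpreter_needed", (1.02, 0.29, 1.76, 0.006), (0.98, 0.25, 1.72, 0.009)),
    ("patient", "learning_disability_patient", (0.10, -0.17, 0.36, 0.481), (0.06, -0.21, 0.33, 0.654)),
    ("patient", "severe_mental_illness", (0.18, -0.36, 0.72, 0.506), (-0.10, -0.64, 0.44, 0.727)),
    ("patient", "ltc_3plus", (0.45, 0.36, 0.54, 1e-4), (0.32, 0.21, 0.43, 1e-4)),
    ("patient", "palliative_care_patient", (-0.58, -1.22, 0.05, 0.07), None),
    ("patient", "personality_disorder", (0.75, 0.37, 1.13, 1e-4), (0.51, 0.12, 0.89, 0.01)),
    ("patient", "polypharmacy", (0.40, 0.25, 0.56, 1e-4), (-0.07, -0.25, 0.11, 0.447)),
    ("patient", "safeguarding_patient", (-0.33, -0.69, 0.04, 0.079), None),
]

#: Intercepts ("mean duration of consultation") of the development-year
#: multivariable models, minutes.
MODEL_INTERCEPTS_2013 = {"consultation": 9.78, "patient": 10.02}


def initial_model_2013() -> pd.DataFrame:
    """Initial development-year regressions, one row per modelled factor."""
    rows = []
    for level, fid, uni, multi in _INITIAL_MODEL_ROWS:
        rows.append(
            {
                "level": level,
                "factor_id": fid,
                "uni_estimate": uni[0],
                "uni_ci_low": uni[1],
                "uni_ci_high": uni[2],
                "uni_p": uni[3],
                "multi_estimate": multi[0] if multi else None,
                "multi_ci_low": multi[1] if multi else None,
                "multi_ci_high": multi[2] if multi else None,
                "multi_p": multi[3] if multi else None,
            }
        )
    return pd.DataFrame(rows)


# Final development-year fixed effects (minutes) of the released measure.
_FINAL_EFFECTS_2013 = {
    "consultation": {
        "drug_alcohol_consult": 4.19,
        "chronic_pain_consult": 0.98,
        "dementia_consult": 1.42,
        "emergency_admission": 7.76,
        "learning_disability_consult": 3.84,
        "mental_health_consult": 3.85,
        "multiple_diagnoses": 2.54,
        "many_drugs_prescribed": 1.73,
        "preventive_tasks": 3.73,
        "first_consult_diabetes": 3.05,
    },
    "patient": {
        "drug_alcohol_patient": 1.89,
        "chronic_pain_patient": 0.72,
        "domestic_violence_patient": 1.43,
        "homelessness_patient": 1.36,
        "interpreter_needed": 0.98,
        "ltc_3plus": 0.30,
        "personality_disorder": 0.51,
    },
}


def final_effects_2013(level: str = "consultation") -> tuple[float, dict[str, float]]:
    """(intercept, factor->effect) of the development-year final model."""
    if level not in _FINAL_EFFECTS_2013:
        raise ValueError(f"unknown level {level!r}")
    return MODEL_INTERCEPTS_2013[level], dict(_FINAL_EFFECTS_2013[level])


def replay_measure_selection(alpha: float = 0.05) -> dict:
    """Replay the published factor-set arithmetic end to end.

    Starts from the recorded consensus outcomes, applies the
    low-prevalence exclusions and consultation-to-patient
    reclassifications, then the negative-coefficient and significance
    rules on the encoded initial regressions, and assembles the retained
    measure. Returns the intermediate sets and the final factor table.
    """
    from .develop import ModelFit, assemble_measure

    final = replay_delphi()
    endorsed = final[final["final_status"] == "endorsed"]
    endorsed_cons = set(endorsed[endorsed["level"] == "consultation"]["factor_id"])
    endorsed_pat = set(endorsed[endorsed["level"] == "patient"]["factor_id"])

    low_prev = set(LOW_PREVALENCE_EXCLUSIONS)
    cons_model = (endorsed_cons - low_prev) - set(RECLASSIFIED_TO_PATIENT)
    pat_model = (endorsed_pat - low_prev) | {
        RECLASSIFIED_TO_PATIENT[f]
        for f in endorsed_cons & set(RECLASSIFIED_TO_PATIENT)
    }

    model = initial_model_2013()
    for level, expected in (("consultation", cons_model), ("patient", pat_model)):
        encoded = set(model[model["level"] == level]["factor_id"])
        if encoded != expected:
            raise AssertionError(
                f"encoded {level} model rows disagree with the replayed sets: "
                f"{sorted(encoded ^ expected)}"
            )

    def _select(level: str) -> ModelFit:
        sub = model[model["level"] == level]
        # one-pass exclusion of negative-relationship factors, then the
        # significance rule on the multivariable terms
        kept = sub[sub["multi_estimate"].notna() & (sub["multi_estimate"] > 0)]
        kept = kept[kept["multi_p"] < alpha]
        terms = kept.rename(
            columns={
                "multi_estimate": "estimate_minutes",
                "multi_ci_low": "ci_low",
                "multi_ci_high": "ci_high",
                "multi_p": "p_value",
            }
        )[["factor_id", "estimate_minutes", "ci_low", "ci_high", "p_value"]]
        intercept = MODEL_INTERCEPTS_2013[level]
        return ModelFit(
            mode="multivariable",
            terms=terms.reset_index(drop=True),
            intercept=(intercept, float("nan"), float("nan"), 1e-4),
            variance_components={},
            n_consultations=0,
            n_patients=0,
            n_practices=0,
            loglik=None,
            converged=True,
        )

    cons_fit = _select("consultation")
    pat_fit = _select("patient")
    retained = assemble_measure(cons_fit, pat_fit)
    return {
        "outcomes": final,
        "endorsed_consultation": endorsed_cons,
        "endorsed_patient": endorsed_pat,
        "modelled_consultation": cons_model,
        "modelled_patient": pat_model,
        "consultation_fit": cons_fit,
        "patient_fit": pat_fit,
        "retained": retained,
    }


# ---------------------------------------------------------------------------
# Toy code-set registry
# ---------------------------------------------------------------------------

_LOOKBACK_YEAR = 365
_LOOKBACK_2Y = 730
_LOOKBACK_3Y = 1095
_LOOKBACK_3M = 91
_LOOKBACK_2M = 61


def toy_registry() -> CodeSetRegistry:
    """Every candidate factor expressed with placeholder codes.

    Code sets are pairwise disjoint and count rules are restricted to
    their own vocabulary, so planted triggers never cross-activate other
    factors — this is what lets the generator record exact truth. The
    real deposited code sets can be swapped in via the same CSV format.
    """
    c = CodeSetRegistry()
    # consultation-level ---------------------------------------------------
    cm = lambda fid, label, codes: c.add(
        FactorDefinition(fid, label, "consultation", "code_match", frozenset(codes))
    )
    cm("homeless_presenting", "Presents with problem of homelessness", {"HP01.", "HP02."})
    cm("safeguarding_concern", "Problem raising safeguarding concerns", {"SGC1.", "SGC2."})
    cm("domestic_violence_concern", "Problem raising domestic violence concerns", {"DVC1.", "DVC2."})
    cm("learning_disability_consult", "About learning disability/autism", {"LDC1.", "LDC2."})
    cm("end_of_life_discussion", "End-of-life issues discussed", {"EOL1.", "EOL2."})
    cm("mental_health_consult", "About mental health problems", {"MHC1.", "MHC2.", "MHC3."})
    cm("dementia_consult", "About dementia", {"DMC1.", "DMC2."})
    cm("drug_alcohol_consult", "About problematic drug or alcohol use", {"DAC1.", "DAC2."})
    cm("minor_surgery", "Procedures or minor surgery carried out", {"MSU1."})
    cm("mus_consult", "Medically unexplained symptoms raised", {"MUC1."})
    cm("outpatient_referral_result", "Results in outpatient referral", {"ORR1."})
    cm("emergency_admission", "Results in emergency hospital admission", {"EMA1.", "EMA2."})
    cm("urgent_secondary_care", "Results in urgent secondary-care assessment", {"USC1."})
    cm("chronic_pain_consult", "About chronic pain management", {"CPC1.", "CPC2."})
    c.add(
        FactorDefinition(
            "multiple_diagnoses",
            ">=2 diagnoses from unique code chapters",
            "consultation",
            "count_rule",
            frozenset({"A101.", "B202.", "C303.", "D404."}),
            count_threshold=2,
            count_unit="chapter",
        )
    )
    c.add(
        FactorDefinition(
            "many_drugs_prescribed",
            ">=3 unique substances prescribed",
            "consultation",
            "count_rule",
            frozenset({"SUB01", "SUB02", "SUB03", "SUB04"}),
            count_threshold=3,
            count_unit="substance",
            source_domain="prescriptions",
        )
    )
    c.add(
        FactorDefinition(
            "preventive_tasks",
            ">=2 preventive/routine tasks carried out",
            "consultation",
            "count_rule",
            frozenset({"PRV1.", "PRV2.", "PRV3."}),
            count_threshold=2,
            count_unit="code",
        )
    )
    c.add(
        FactorDefinition(
            "first_consult_cancer",
            "First consultation after cancer diagnosis",
            "consultation",
            "first_consult_after_dx",
            frozenset({"FCC1.", "FCC2."}),
        )
    )
    c.add(
        FactorDefinition(
            "first_consult_diabetes",
            "First consultation after diabetes diagnosis",
            "consultation",
            "first_consult_after_dx",
            frozenset({"FCD1."}),
        )
    )
    # patient-level --------------------------------------------------------
    pm = lambda fid, label, codes, lookback: c.add(
        FactorDefinition(
            fid, label, "patient", "code_match", frozenset(codes), lookback_days=lookback
        )
    )
    pm("homelessness_patient", "Homelessness (previous year)", {"HMP1."}, _LOOKBACK_YEAR)
    pm("safeguarding_patient", "Safeguarding (previous 3 years)", {"SGP1."}, _LOOKBACK_3Y)
    pm("domestic_violence_patient", "Domestic violence (previous year)", {"DVP1."}, _LOOKBACK_YEAR)
    pm("interpreter_needed", "Interpreter needed/no English (last 3 years)", {"INT1."}, _LOOKBACK_3Y)
    pm("learning_disability_patient", "Learning disability/autism (ever)", {"LDP1."}, None)
    pm("dementia_patient", "Dementia (ever)", {"DMP1."}, None)
    pm("palliative_care_patient", "Receiving palliative care (ever)", {"PCP1."}, None)
    pm("drug_alcohol_patient", "Drug misuse/alcoholism (previous year)", {"DAP1."}, _LOOKBACK_YEAR)
    pm("severe_mental_illness", "Severe mental illness (previous 3 years)", {"SMI1."}, _LOOKBACK_3Y)
    pm("wheelchair_use", "Wheelchair use (previous 2 years)", {"WCU1."}, _LOOKBACK_2Y)
    pm("recent_outpatient_referral", "Recent outpatient referral", {"ROR1."}, _LOOKBACK_YEAR)
    pm("warfarin_use", "Currently on warfarin", {"WAR1."}, _LOOKBACK_2M)
    pm("cancer_ever", "Cancer (ever)", {"CAE1."}, None)
    pm("diabetes_ever", "Diabetes (ever)", {"DBE1."}, None)
    pm("deafness", "Deafness (ever)", {"DEA1."}, None)
    pm("paraplegia", "Paraplegia (ever)", {"PAR1."}, None)
    pm("blind_partial_sight", "Blind or partially sighted (ever)", {"BPS1."}, None)
    pm("immunosuppressant", "On immunosuppressant medication", {"IMS1."}, _LOOKBACK_2M)
    pm("housebound_nursing_home", "Housebound or nursing home (previous 3 years)", {"HNH1."}, _LOOKBACK_3Y)
    pm("personality_disorder", "Personality/disruptive disorder (ever)", {"PDD1."}, None)
    pm("mus_patient", "Medically unexplained symptoms (last year)", {"MUP1."}, _LOOKBACK_YEAR)
    pm("morbid_obesity", "Morbidly obese", {"MOB1."}, None)
    pm("chronic_pain_patient", "Chronic pain (last year)", {"CPP1."}, _LOOKBACK_YEAR)
    c.add(
        FactorDefinition(
            "ltc_3plus",
            ">=3 major long-term conditions",
            "patient",
            "count_rule",
            frozenset({"LTA1.", "LTB1.", "LTC1.", "LTD1."}),
            count_threshold=3,
            count_unit="group",
            code_groups={"LTA1.": "ltc_a", "LTB1.": "ltc_b", "LTC1.": "ltc_c", "LTD1.": "ltc_d"},
        )
    )
    c.add(
        FactorDefinition(
            "frequent_attender",
            "Frequent attender (>=14 consultations in last year)",
            "patient",
            "percentile_rule",
            lookback_days=_LOOKBACK_YEAR,
            count_threshold=14,
            count_unit="consultation",
            source_domain="consultations",
            percentile=0.95,
        )
    )
    c.add(
        FactorDefinition(
            "polypharmacy",
            "Polypharmacy (>=9 unique substances in previous 3 months)",
            "patient",
            "percentile_rule",
            frozenset({f"PLY{i:02d}" for i in range(1, 11)}),
            lookback_days=_LOOKBACK_3M,
            count_threshold=9,
            count_unit="substance",
            source_domain="prescriptions",
            percentile=0.95,
        )
    )
    return c


def reclassification_map(registry: CodeSetRegistry | None = None) -> dict[str, FactorDefinition]:
    """The published consultation-to-patient reclassifications, expressed
    against the toy registry's patient-level definitions."""
    registry = registry or toy_registry()
    return {
        cons_id: registry[patient_id]
        for cons_id, patient_id in RECLASSIFIED_TO_PATIENT.items()
    }


# ---------------------------------------------------------------------------
# Reference simulation configuration
# ---------------------------------------------------------------------------

#: Plausible per-consultation trigger prevalences used by the reference
#: simulation (chosen for stable estimation, not to reproduce any
#: confidential prevalence table; the emergency-admission factor is
#: planted at an elevated 1% so its effect is estimable at desk scale).
REFERENCE_PREVALENCES = {
    "drug_alcohol_consult": 0.02,
    "chronic_pain_consult": 0.08,
    "dementia_consult": 0.01,
    "emergency_admission": 0.01,
    "learning_disability_consult": 0.01,
    "mental_health_consult": 0.15,
    "multiple_diagnoses": 0.20,
    "many_drugs_prescribed": 0.15,
    "preventive_tasks": 0.10,
    "first_consult_diabetes": 0.01,
}


def reference_simulation_config(
    seed: int,
    n_practices: int = 50,
    patients_per_practice: int = 400,
    consult_rate_per_year: float = 5.1,
    sd_practice: float = 0.5,
    sd_patient: float = 1.0,
    sd_residual: float = 3.0,
) -> SimulationConfig:
    """Simulation truth set to the published final consultation-factor
    model (defaults yield roughly 100 000 consultations in 50 practices)."""
    baseline, effects = final_effects_2013("consultation")
    return SimulationConfig(
        n_practices=n_practices,
        patients_per_practice=patients_per_practice,
        consult_rate_per_year=consult_rate_per_year,
        factor_prevalence=dict(REFERENCE_PREVALENCES),
        duration_baseline_minutes=baseline,
        factor_effects_minutes=effects,
        sd_practice=sd_practice,
        sd_patient=sd_patient,
        sd_residual=sd_residual,
        study_window=("2013-04-01", "2014-04-01"),
        seed=seed,
    )
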