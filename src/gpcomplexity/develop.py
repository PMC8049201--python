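"""Measure-development pipeline.

Order of operations, mirroring the published workflow:

1. prevalence screen — factors present in fewer than 0.05% of
   consultations (consultation factors) or patients (patient factors)
   are excluded (strict ``<``; exactly 0.05% is retained);
2. percentile re-specification — qualitative count factors (frequent
   attender, polypharmacy) get integer thresholds from the 95th centile
   of per-patient counts;
3. reclassification — selected low-prevalence consultation factors are
   moved to the patient level with a lookback window;
4. mixed-effects duration regressions — consultation and patient factors
   in separate models, random intercepts for practice and for patient
   (nested within practice), REML by default, Wald intervals;
5. negative-coefficient exclusion (one pass on the initial multivariable
   fit) followed by backward stepwise elimination at P < 0.05, removing
   the single worst factor per refit;
6. assembly of the final retained factor set, with explicit overrides
   allowed (recorded with provenance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codesets import CodeSetRegistry, FactorDefinition
from .nested_lmm import NestedLMMResult, fit_nested_lmm

__all__ = [
    "PipelineConfig",
    "ModelFit",
    "prevalence_screen",
    "specify_percentile_threshold",
    "reclassify_low_prevalence",
    "make_design",
    "fit_duration_model",
    "backward_stepwise",
    "assemble_measure",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tuning knobs of the development pipeline."""

    exclusion_threshold: float = 0.0005
    stepwise_alpha: float = 0.05
    frequent_attender_percentile: float = 0.95
    polypharmacy_percentile: float = 0.95
    reml: bool = True

    def __post_init__(self) -> None:
        for name in (
            "exclusion_threshold",
            "stepwise_alpha",
            "frequent_attender_percentile",
            "polypharmacy_percentile",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


# --------------------------------------------------------------------------
# prevalence screening
# --------------------------------------------------------------------------

def prevalence_screen(
    flags: pd.DataFrame,
    registry: CodeSetRegistry,
    consultations: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-factor prevalence with the strict ``< threshold`` exclusion flag.

    Consultation factors use the consultation denominator; patient
    factors use the patient denominator, where a patient counts once if
    the factor holds at any of their consultations.
    """
    config = config or PipelineConfig()
    if len(flags) == 0:
        raise ValueError("no flagged consultations (zero denominator)")
    cons = consultations.set_index("consultation_id")
    patient_of = cons["patient_id"].reindex(flags.index)
    n_cons = len(flags)
    n_patients = int(patient_of.nunique())
    if n_patients == 0:
        raise ValueError("zero patient denominator")
    rows = []
    for d in registry:
        if d.factor_id not in flags.columns:
            raise ValueError(f"factor {d.factor_id!r} missing from flags")
        col = flags[d.factor_id].astype(bool)
        if d.level == "consultation":
            numerator = int(col.sum())
            denominator = n_cons
        else:
            numerator = int(patient_of[col].nunique())
            denominator = n_patients
        prevalence = numerator / denominator
        rows.append(
            {
                "factor_id": d.factor_id,
                "level": d.level,
                "numerator": numerator,
                "denominator": denominator,
                "prevalence": prevalence,
                "excluded": prevalence < config.exclusion_threshold,
            }
        )
    return pd.DataFrame(rows)


def specify_percentile_threshold(counts, percentile: float = 0.95) -> int:
    """Integer threshold at the empirical percentile of per-patient counts.

    Returns the smallest observed integer ``t`` whose empirical CDF
    reaches ``percentile`` (the nearest-rank percentile), so "at or above
    the Pth centile" means ``statistic >= t``. For counts 1..100 once
    each, the 95th centile gives 95.
    """
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty statistic table")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be nonnegative numbers")
    return int(np.percentile(arr, 100.0 * percentile, method="inverted_cdf"))


# --------------------------------------------------------------------------
# reclassification
# --------------------------------------------------------------------------

def reclassify_low_prevalence(
    registry: CodeSetRegistry,
    reclassification: dict[str, FactorDefinition],
) -> CodeSetRegistry:
    """Move consultation factors to the patient level.

    ``reclassification`` maps a consultation-level factor id to its
    patient-level definition (with lookback window). If a patient-level
    factor with the target id already exists it must carry the same
    window (otherwise an error); the consultation-level entry is removed
    either way. An empty map returns the registry unchanged.
    """
    out = registry.copy()
    for cons_id, patient_def in reclassification.items():
        if cons_id not in out:
            raise ValueError(f"reclassification names unknown factor {cons_id!r}")
        if out[cons_id].level != "consultation":
            raise ValueError(f"{cons_id!r} is not a consultation-level factor")
        if patient_def.level != "patient":
            raise ValueError(
                f"reclassification target for {cons_id!r} must be patient-level"
            )
        if patient_def.factor_id in out:
            existing = out[patient_def.factor_id]
            if existing.level == "patient" and (
                existing.lookback_days != patient_def.lookback_days
            ):
                raise ValueError(
                    f"{patient_def.factor_id!r} already exists at patient level "
                    f"with a conflicting window ({existing.lookback_days} vs "
                    f"{patient_def.lookback_days} days)"
                )
        out.remove(cons_id)
        if patient_def.factor_id not in out:
            out.add(patient_def)
    return out


# --------------------------------------------------------------------------
# mixed-effects duration models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    """Fixed-effect estimates and variance components from one duration
    regression (or a family of univariable regressions)."""

    mode: str  # "multivariable" | "univariable"
    terms: pd.DataFrame = field(repr=False)
    intercept: tuple[float, float, float, float] | None  # est, lo, hi, p
    variance_components: dict[str, float]
    n_consultations: int
    n_patients: int
    n_practices: int
    loglik: float | None
    converged: bool
    reml: bool = True

    @property
    def factor_ids(self) -> list[str]:
        return list(self.terms["factor_id"])


def make_design(
    patients: pd.DataFrame,
    consultations: pd.DataFrame,
    flags: pd.DataFrame,
    factor_ids,
) -> pd.DataFrame:
    """Assemble the modelling frame: practice, patient, duration, and one
    0/1 column per factor."""
    factor_ids = list(factor_ids)
    missing = [f for f in factor_ids if f not in flags.columns]
    if missing:
        raise ValueError(f"factors missing from flags: {missing}")
    cons = consultations.set_index("consultation_id")
    design = pd.DataFrame(index=flags.index)
    design["patient_id"] = cons["patient_id"].reindex(flags.index)
    design["practice_id"] = (
        patients.set_index("patient_id")["practice_id"]
        .reindex(design["patient_id"])
        .to_numpy()
    )
    design["duration_minutes"] = cons["duration_minutes"].reindex(flags.index)
    for f in factor_ids:
        design[f] = flags[f].astype(float)
    return design.reset_index(drop=True)


def _fit_one(design: pd.DataFrame, factor_ids, reml, fix_gamma=None) -> tuple:
    y = design["duration_minutes"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(design))] + [design[f].to_numpy(dtype=float) for f in factor_ids]
    )
    for f in factor_ids:
        col = design[f].to_numpy()
        if col.min() == col.max():
            raise ValueError(
                f"singular design: factor {f!r} is constant across all consultations"
            )
    res = fit_nested_lmm(
        y,
        X,
        design["practice_id"].to_numpy(),
        design["patient_id"].to_numpy(),
        reml=reml,
        fix_gamma=fix_gamma,
    )
    return res


def _terms_from(res: NestedLMMResult, factor_ids) -> tuple[pd.DataFrame, tuple]:
    ci = res.conf_int()
    p = res.p_values
    intercept = (float(res.beta[0]), float(ci[0, 0]), float(ci[0, 1]), float(p[0]))
    terms = pd.DataFrame(
        {
            "factor_id": list(factor_ids),
            "estimate_minutes": res.beta[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p_value": p[1:],
        }
    )
    return terms, intercept


def fit_duration_model(
    patients: pd.DataFrame,
    consultations: pd.DataFrame,
    flags: pd.DataFrame,
    factor_ids,
    mode: str = "multivariable",
    reml: bool = True,
    fix_gamma=None,
) -> ModelFit:
    """Mixed-effects regression of duration on binary factor indicators.

    Random intercepts for practice and for patient nested within
    practice; REML by default; Wald 95% intervals and p-values.
    ``multivariable`` fits all factors jointly; ``univariable`` fits one
    factor at a time and collects the per-factor estimates (no shared
    intercept is reported). Consultation- and patient-level factor sets
    should be fitted separately, never jointly.
    """
    factor_ids = list(factor_ids)
    if mode not in ("multivariable", "univariable"):
        raise ValueError(f"unknown mode {mode!r}")
    design = make_design(patients, consultations, flags, factor_ids)
    if design["practice_id"].nunique() < 2:
        raise ValueError("need at least two practices")
    if mode == "multivariable":
        res = _fit_one(design, factor_ids, reml, fix_gamma)
        terms, intercept = _terms_from(res, factor_ids)
        return ModelFit(
            mode=mode,
            terms=terms,
            intercept=intercept,
            variance_components={
                "practice": res.var_practice,
                "patient": res.var_patient,
                "residual": res.var_residual,
            },
            n_consultations=res.n_obs,
            n_patients=res.n_patients,
            n_practices=res.n_practices,
            loglik=res.loglik,
            converged=res.converged,
            reml=reml,
        )
    rows = []
    last = None
    for f in factor_ids:
        res = _fit_one(design, [f], reml, fix_gamma)
        terms, _ = _terms_from(res, [f])
        rows.append(terms)
        last = res
    return ModelFit(
        mode=mode,
        terms=pd.concat(rows, ignore_index=True),
        intercept=None,
        variance_components={},
        n_consultations=len(design),
        n_patients=int(design["patient_id"].nunique()),
        n_practices=int(design["practice_id"].nunique()),
        loglik=None,
        converged=last.converged if last is not None else True,
        reml=reml,
    )


def backward_stepwise(
    patients: pd.DataFrame,
    consultations: pd.DataFrame,
    flags: pd.DataFrame,
    factor_ids,
    alpha: float = 0.05,
    reml: bool = True,
) -> tuple[ModelFit, pd.DataFrame]:
    """Negative-coefficient exclusion, then backward stepwise elimination.

    Factors with a negative coefficient in the initial multivariable fit
    are removed together in one pass (step 0). Thereafter the model is
    refitted repeatedly, removing the single factor with the highest
    p-value >= alpha, until every remaining factor has p < alpha. Returns
    the final fit and an ordered removal log (step, factor, reason,
    estimate and p at removal). If every factor is removed, the
    intercept-only fit is returned with a warning.
    """
    remaining = list(factor_ids)
    log_rows = []
    fit = fit_duration_model(
        patients, consultations, flags, remaining, "multivariable", reml
    )
    negatives = fit.terms[fit.terms["estimate_minutes"] < 0]
    for _, row in negatives.iterrows():
        log_rows.append(
            {
                "step": 0,
                "factor_id": row["factor_id"],
                "reason": "negative_coefficient",
                "estimate_minutes": row["estimate_minutes"],
                "p_value": row["p_value"],
            }
        )
    if len(negatives):
        remaining = [f for f in remaining if f not in set(negatives["factor_id"])]
        if remaining:
            fit = fit_duration_model(
                patients, consultations, flags, remaining, "multivariable", reml
            )

    step = 1
    while remaining:
        worst = fit.terms.sort_values("p_value", ascending=False).iloc[0]
        if worst["p_value"] < alpha:
            break
        log_rows.append(
            {
                "step": step,
                "factor_id": worst["factor_id"],
                "reason": "p_above_alpha",
                "estimate_minutes": worst["estimate_minutes"],
                "p_value": worst["p_value"],
            }
        )
        remaining = [f for f in remaining if f != worst["factor_id"]]
        step += 1
        if remaining:
            fit = fit_duration_model(
                patients, consultations, flags, remaining, "multivariable", reml
            )

    if not remaining:
        warnings.warn(
            "backward stepwise removed every factor; returning the intercept-only model",
            RuntimeWarning,
            stacklevel=2,
        )
        design = make_design(patients, consultations, flags, [])
        res = _fit_one(design, [], reml)
        terms, intercept = _terms_from(res, [])
        fit = ModelFit(
            mode="multivariable",
            terms=terms,
            intercept=intercept,
            variance_components={
                "practice": res.var_practice,
                "patient": res.var_patient,
                "residual": res.var_residual,
            },
            n_consultations=res.n_obs,
            n_patients=res.n_patients,
            n_practices=res.n_practices,
            loglik=res.loglik,
            converged=res.converged,
            reml=reml,
        )
    return fit, pd.DataFrame(
        log_rows,
        columns=["step", "factor_id", "reason", "estimate_minutes", "p_value"],
    )


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def assemble_measure(
    consultation_fit: ModelFit | None,
    patient_fit: ModelFit | None,
    overrides=(),
    registry: CodeSetRegistry | None = None,
) -> pd.DataFrame:
    """Union of surviving consultation and patient factors, plus explicit
    force-retained overrides (provenance recorded).

    Returns a DataFrame with ``factor_id`` and ``source`` in
    {consultation_model, patient_model, override}.
    """
    rows: dict[str, str] = {}
    for fit, source in (
        (consultation_fit, "consultation_model"),
        (patient_fit, "patient_model"),
    ):
        if fit is None:
            continue
        for fid in fit.factor_ids:
            if fid in rows:
                raise ValueError(
                    f"factor {fid!r} appears in both final models; the consultation "
                    "and patient factor sets must be disjoint"
                )
            rows[fid] = source
    for fid in overrides:
        if registry is not None and fid not in registry:
            raise ValueError(f"override names unknown factor {fid!r}")
        rows.setdefault(fid, "override")
    return pd.DataFrame(
        {"factor_id": sorted(rows), "source": [rows[f] for f in sorted(rows)]}
    )
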