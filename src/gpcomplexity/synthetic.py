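"""Synthetic primary-care data with known ground truth.

Generates an age–sex stratified patient panel across practices, face-to-
face consultations whose durations follow

    baseline + sum_f effect_f * flag_f + u_practice + v_patient + noise,

coded events planted inside consultations (consultation factors) or in
patient history at controlled offsets inside lookback windows (patient
factors), and prescriptions for the count-based rules. Every planted
factor's per-consultation truth is recorded, so the downstream flagging,
screening and model-fitting stages can be tested exactly without any
external data.

All randomness flows through one seeded generator with a fixed draw
order (practice effects, patients, patient effects, consultation counts,
consultation dates, patient-factor carriers, consultation-factor flags,
residuals, then event code choices factor by factor in sorted order), so
identical configs produce bit-identical tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codesets import CodeSetRegistry, chapter_of

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "default_age_sex_weights",
    "simulate_dataset",
    "simulate_votes",
    "write_dataset",
    "read_dataset",
    "VOTE_SCORE_DISTRIBUTIONS",
]

#: Default age bands: 10-year bands to >=85 (first two follow the
#: conventional 0-4 / 5-14 split used for primary-care attendance tables).
DEFAULT_AGE_BANDS = (
    "0-4", "5-14", "15-24", "25-34", "35-44",
    "45-54", "55-64", "65-74", "75-84", "85+",
)

SEXES = ("F", "M")


def parse_age_band(band: str) -> tuple[int, int]:
    """Return the inclusive (low, high) ages of a band like ``"25-34"`` or
    ``"85+"`` (open bands are capped at low + 15 for sampling)."""
    band = band.strip()
    if band.endswith("+"):
        lo = int(band[:-1])
        return lo, lo + 15
    lo_s, hi_s = band.split("-")
    lo, hi = int(lo_s), int(hi_s)
    if hi < lo:
        raise ValueError(f"invalid age band {band!r}")
    return lo, hi


def default_age_sex_weights() -> dict[tuple[str, str], float]:
    """A flat panel: every (default age band, sex) cell equally likely."""
    cells = [(band, sex) for band in DEFAULT_AGE_BANDS for sex in SEXES]
    return {cell: 1.0 / len(cells) for cell in cells}


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic dataset.

    ``factor_prevalence`` is interpreted per consultation for
    consultation-level factors and per patient (carrier probability) for
    patient-level factors. Every key of ``factor_effects_minutes`` must
    also appear in ``factor_prevalence``.
    """

    n_practices: int
    patients_per_practice: int
    consult_rate_per_year: float
    factor_prevalence: dict[str, float]
    duration_baseline_minutes: float
    factor_effects_minutes: dict[str, float]
    sd_practice: float
    sd_patient: float
    sd_residual: float
    study_window: tuple[dt.date, dt.date]
    seed: int
    age_sex_weights: dict[tuple[str, str], float] = field(
        default_factory=default_age_sex_weights
    )
    duration_floor_minutes: float = 1.0
    duration_cap_minutes: float | None = None
    #: Per-factor offset (days before the consultation) at which patient-
    #: factor history events are planted; defaults to lookback // 2.
    patient_event_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "study_window",
            (_as_date(self.study_window[0]), _as_date(self.study_window[1])),
        )
        self.validate()

    def validate(self) -> None:
        if self.n_practices < 1 or self.patients_per_practice < 1:
            raise ValueError("need at least one practice and one patient per practice")
        if not np.isfinite(self.consult_rate_per_year) or self.consult_rate_per_year <= 0:
            raise ValueError("consult_rate_per_year must be positive and finite")
        if not np.isfinite(self.duration_baseline_minutes) or self.duration_baseline_minutes <= 0:
            raise ValueError("duration_baseline_minutes must be positive and finite")
        for name in ("sd_practice", "sd_patient", "sd_residual"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be nonnegative and finite")
        if self.sd_residual == 0 and (self.sd_practice or self.sd_patient):
            pass  # allowed: degenerate residual with structured noise
        for fid, p in self.factor_prevalence.items():
            if not np.isfinite(p) or not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {fid!r} must lie in [0, 1]")
        for fid, eff in self.factor_effects_minutes.items():
            if not np.isfinite(eff):
                raise ValueError(f"effect of {fid!r} must be finite")
            if fid not in self.factor_prevalence:
                raise ValueError(
                    f"factor {fid!r} has an effect but no prevalence entry"
                )
        start, end = self.study_window
        if start >= end:
            raise ValueError("study_window start must precede end")
        if not self.age_sex_weights:
            raise ValueError("age_sex_weights must be non-empty")
        total = float(sum(self.age_sex_weights.values()))
        if not np.isfinite(total) or total <= 0:
            raise ValueError("age_sex_weights must sum to a positive finite value")
        for (band, sex), w in self.age_sex_weights.items():
            if w < 0:
                raise ValueError(f"negative weight for cell ({band}, {sex})")
            parse_age_band(band)
        if self.duration_floor_minutes <= 0:
            raise ValueError("duration_floor_minutes must be positive")


@dataclass
class SyntheticDataset:
    """Generated record tables plus the configuration and per-consultation
    planted truth used to produce them."""

    patients: pd.DataFrame
    consultations: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    truth_flags: pd.DataFrame  # index consultation_id, one bool column per factor
    truth: SimulationConfig


def _plantable(definition, prevalence) -> None:
    if prevalence <= 0:
        return
    if definition.source_domain == "consultations":
        raise ValueError(
            f"factor {definition.factor_id!r} counts consultations; its prevalence "
            "emerges from the consultation process and cannot be planted directly "
            "(set its prevalence to 0)"
        )
    if definition.rule_kind in ("count_rule", "percentile_rule") and not definition.codes:
        raise ValueError(
            f"factor {definition.factor_id!r}: planting a count rule requires a "
            "code/substance vocabulary"
        )


def simulate_dataset(
    config: SimulationConfig, registry: CodeSetRegistry | None = None
) -> SyntheticDataset:
    """Generate a synthetic dataset with known per-consultation truth.

    ``registry`` supplies the trigger rules used to plant codes; the
    bundled toy registry is used when omitted. Identical ``config`` (and
    registry) produce bit-identical output.
    """
    if registry is None:
        from .reference import toy_registry

        registry = toy_registry()
    for fid in config.factor_prevalence:
        if fid not in registry:
            raise ValueError(f"factor {fid!r} not present in the code-set registry")
        _plantable(registry[fid], config.factor_prevalence[fid])

    rng = np.random.default_rng(config.seed)
    start, end = config.study_window
    window_days = (end - start).days
    years = window_days / 365.25

    # --- practices and patients -----------------------------------------
    n_practices = config.n_practices
    n_patients = n_practices * config.patients_per_practice
    u = rng.normal(0.0, config.sd_practice, n_practices)

    cells = sorted(config.age_sex_weights)
    probs = np.array([config.age_sex_weights[c] for c in cells], dtype=float)
    probs = probs / probs.sum()
    cell_idx = rng.choice(len(cells), size=n_patients, p=probs)
    lohi = np.array([parse_age_band(band) for band, _ in cells])
    ages = rng.integers(lohi[cell_idx, 0], lohi[cell_idx, 1] + 1)
    v = rng.normal(0.0, config.sd_patient, n_patients)

    patient_ids = np.arange(1, n_patients + 1)
    practice_of_patient = np.repeat(np.arange(1, n_practices + 1), config.patients_per_practice)
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "practice_id": practice_of_patient,
            "sex": [cells[i][1] for i in cell_idx],
            "birth_year": start.year - ages,
            "reg_start": pd.Timestamp(start),
            "reg_end": pd.Timestamp(end),
        }
    )

    # --- consultations ---------------------------------------------------
    counts = rng.poisson(config.consult_rate_per_year * years, n_patients)
    n_cons = int(counts.sum())
    if n_cons == 0:
        raise ValueError("simulation produced no consultations; raise the rate")
    day_offsets = rng.integers(0, window_days, n_cons)
    cons_patient = np.repeat(patient_ids, counts)
    # sort dates within each patient for readability/determinism
    order = np.lexsort((day_offsets, cons_patient))
    cons_patient = cons_patient[order]
    day_offsets = day_offsets[order]
    cons_ids = np.arange(1, n_cons + 1)
    cons_dates = pd.Timestamp(start) + pd.to_timedelta(day_offsets, unit="D")
    cons_practice = practice_of_patient[cons_patient - 1]

    # --- factor truth ----------------------------------------------------
    factor_ids = sorted(config.factor_prevalence)
    truth = pd.DataFrame(
        False, index=pd.Index(cons_ids, name="consultation_id"), columns=factor_ids
    )
    carrier: dict[str, np.ndarray] = {}
    for fid in factor_ids:
        d = registry[fid]
        p = config.factor_prevalence[fid]
        if d.level == "patient":
            carrier[fid] = rng.random(n_patients) < p
            truth[fid] = carrier[fid][cons_patient - 1]
    for fid in factor_ids:
        d = registry[fid]
        p = config.factor_prevalence[fid]
        if d.level == "consultation":
            drawn = rng.random(n_cons) < p
            if d.rule_kind == "first_consult_after_dx":
                # the diagnosis is planted on the drawn consultation's date;
                # the rule flags the first consultation on/after that date
                # (ties broken by lowest consultation id), so move the truth
                # to that representative.
                drawn = _first_of_same_day(drawn, cons_patient, day_offsets)
            truth[fid] = drawn

    # --- durations -------------------------------------------------------
    eps = rng.normal(0.0, config.sd_residual, n_cons)
    durations = np.full(n_cons, config.duration_baseline_minutes)
    for fid, eff in sorted(config.factor_effects_minutes.items()):
        durations = durations + eff * truth[fid].to_numpy()
    durations = durations + u[cons_practice - 1] + v[cons_patient - 1] + eps
    durations = np.maximum(durations, config.duration_floor_minutes)
    if config.duration_cap_minutes is not None:
        durations = np.minimum(durations, config.duration_cap_minutes)

    consultations = pd.DataFrame(
        {
            "consultation_id": cons_ids,
            "patient_id": cons_patient,
            "date": cons_dates,
            "duration_minutes": durations,
        }
    )

    # --- plant coded events and prescriptions ---------------------------
    planter = _Planter(rng, start)
    for fid in factor_ids:
        d = registry[fid]
        if d.level == "consultation":
            flagged = truth[fid].to_numpy()
            planter.plant_consultation_factor(
                d, cons_ids[flagged], cons_patient[flagged], cons_dates[flagged]
            )
        else:
            mask = carrier[fid][cons_patient - 1]
            offset = config.patient_event_offsets.get(fid)
            planter.plant_patient_factor(
                d,
                patient_ids[carrier[fid]],
                cons_ids[mask],
                cons_patient[mask],
                cons_dates[mask],
                offset,
            )

    events, prescriptions = planter.tables()
    return SyntheticDataset(
        patients=patients,
        consultations=consultations,
        events=events,
        prescriptions=prescriptions,
        truth_flags=truth,
        truth=config,
    )


def _first_of_same_day(drawn, cons_patient, day_offsets):
    """Move each drawn flag to the lowest consultation id among the same
    patient/day (the consultation the first-after-diagnosis rule selects
    when the diagnosis is coded that day)."""
    out = np.zeros_like(drawn)
    df = pd.DataFrame(
        {"patient": cons_patient, "day": day_offsets, "pos": np.arange(len(drawn))}
    )
    rep = df.groupby(["patient", "day"], sort=False)["pos"].transform("min")
    out[rep.to_numpy()[drawn]] = True
    return out


class _Planter:
    """Accumulates planted events and prescriptions."""

    def __init__(self, rng, study_start: dt.date) -> None:
        self.rng = rng
        self.pre_study = pd.Timestamp(study_start) - pd.Timedelta(days=365)
        self.ev: list[tuple] = []  # (patient_id, consultation_id|None, date, code)
        self.rx: list[tuple] = []  # (patient_id, consultation_id|None, date, substance)

    # -- helpers ---------------------------------------------------------

    def _choose_codes(self, definition, k: int) -> np.ndarray:
        codes = sorted(definition.codes)
        return self.rng.choice(codes, size=k)

    def _count_rule_codes(self, definition) -> list[str]:
        """A fixed set of codes that satisfies a distinct-count rule."""
        t = definition.count_threshold
        codes = sorted(definition.codes)
        if definition.count_unit == "chapter":
            by_chapter: dict[str, str] = {}
            for c in codes:
                by_chapter.setdefault(chapter_of(c), c)
            picks = [by_chapter[ch] for ch in sorted(by_chapter)][:t]
        elif definition.count_unit == "group":
            by_group: dict[str, str] = {}
            for c in codes:
                by_group.setdefault(definition.code_groups.get(c, c), c)
            picks = [by_group[g] for g in sorted(by_group)][:t]
        else:  # code / substance
            picks = codes[:t]
        if len(picks) < t:
            raise ValueError(
                f"factor {definition.factor_id!r}: code set cannot satisfy its own "
                f"count rule (needs {t} distinct {definition.count_unit}s)"
            )
        return picks

    # -- consultation-level ----------------------------------------------

    def plant_consultation_factor(self, definition, cons_ids, patient_ids, dates):
        k = len(cons_ids)
        if k == 0:
            return
        if definition.rule_kind == "code_match":
            codes = self._choose_codes(definition, k)
            target = self.rx if definition.source_domain == "prescriptions" else self.ev
            for cid, pid, date, code in zip(cons_ids, patient_ids, dates, codes):
                target.append((pid, cid, date, code))
        elif definition.rule_kind in ("count_rule", "percentile_rule"):
            picks = self._count_rule_codes(definition)
            target = self.rx if definition.source_domain == "prescriptions" else self.ev
            for cid, pid, date in zip(cons_ids, patient_ids, dates):
                for code in picks:
                    target.append((pid, cid, date, code))
        elif definition.rule_kind == "first_consult_after_dx":
            codes = self._choose_codes(definition, k)
            for pid, date, code in zip(patient_ids, dates, codes):
                self.ev.append((pid, None, date, code))  # history-dated diagnosis
        else:  # pragma: no cover - guarded by FactorDefinition validation
            raise ValueError(f"cannot plant rule kind {definition.rule_kind!r}")

    # -- patient-level ----------------------------------------------------

    def plant_patient_factor(
        self, definition, carrier_ids, cons_ids, cons_patients, cons_dates, offset
    ):
        target = self.rx if definition.source_domain == "prescriptions" else self.ev
        if definition.is_ever:
            # one history record per carrier, pre-dating the study window
            if definition.rule_kind == "code_match":
                codes = self._choose_codes(definition, len(carrier_ids))
                for pid, code in zip(carrier_ids, codes):
                    target.append((pid, None, self.pre_study, code))
            else:
                picks = self._count_rule_codes(definition)
                for pid in carrier_ids:
                    for code in picks:
                        target.append((pid, None, self.pre_study, code))
            return
        lookback = definition.lookback_days
        if offset is None:
            offset = lookback // 2
        if not (0 <= offset < lookback):
            raise ValueError(
                f"factor {definition.factor_id!r}: planting offset {offset} must lie "
                f"in [0, {lookback}) to fall inside the half-open window"
            )
        delta = pd.Timedelta(days=offset)
        if definition.rule_kind == "code_match":
            codes = self._choose_codes(definition, len(cons_ids))
            for pid, date, code in zip(cons_patients, cons_dates, codes):
                target.append((pid, None, date - delta, code))
        else:
            picks = self._count_rule_codes(definition)
            for pid, date in zip(cons_patients, cons_dates):
                for code in picks:
                    target.append((pid, None, date - delta, code))

    # -- output -----------------------------------------------------------

    def tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        events = pd.DataFrame(
            self.ev, columns=["patient_id", "consultation_id", "date", "code"]
        )
        prescriptions = pd.DataFrame(
            self.rx, columns=["patient_id", "consultation_id", "date", "substance_id"]
        )
        for df, id_col in ((events, "event_id"), (prescriptions, "rx_id")):
            df["consultation_id"] = df["consultation_id"].astype("Int64")
            df.insert(0, id_col, np.arange(1, len(df) + 1))
        return events, prescriptions


# --------------------------------------------------------------------------
# Delphi vote simulation
# --------------------------------------------------------------------------

#: Score distributions per truth category. ``clear_endorse`` and
#: ``clear_reject`` are rejection-sampled until the drawn panel satisfies
#: the corresponding strict threshold rule, so classification of such
#: factors is guaranteed; ``borderline`` panels land on either side of the
#: thresholds with enumerable probability.
VOTE_SCORE_DISTRIBUTIONS: dict[str, dict[int, float]] = {
    "clear_endorse": {2: 0.10, 3: 0.30, 4: 0.38, 5: 0.22},
    "clear_reject": {1: 0.55, 2: 0.35, 3: 0.10},
    "borderline": {1: 0.15, 2: 0.20, 3: 0.35, 4: 0.20, 5: 0.10},
}


def _satisfies(scores: np.ndarray, category: str) -> bool:
    n = len(scores)
    prop_endorse = np.isin(scores, (3, 4, 5)).sum() / n
    prop_reject = (scores == 1).sum() / n
    if category == "clear_endorse":
        return prop_endorse > 0.70 and prop_reject < 0.20
    if category == "clear_reject":
        return prop_endorse < 0.40 and prop_reject > 0.20
    return True


def simulate_votes(
    n_panelists: int,
    factor_truth: dict[str, str],
    seed: int,
    round: int = 1,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Simulate one round of panel votes with known per-factor truth.

    ``factor_truth`` maps factor_id to ``clear_endorse``, ``clear_reject``
    or ``borderline``. Clear factors are guaranteed to classify as
    endorsed/rejected under the default thresholds; borderline factors
    straddle them. Reproducible by seed.
    """
    if n_panelists < 1:
        raise ValueError("n_panelists must be >= 1")
    unknown = {c for c in factor_truth.values() if c not in VOTE_SCORE_DISTRIBUTIONS}
    if unknown:
        raise ValueError(f"unknown factor categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    frames = []
    for fid in sorted(factor_truth):
        category = factor_truth[fid]
        dist = VOTE_SCORE_DISTRIBUTIONS[category]
        values = np.array(sorted(dist))
        probs = np.array([dist[s] for s in values])
        for _ in range(max_tries):
            scores = rng.choice(values, size=n_panelists, p=probs)
            if _satisfies(scores, category):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not satisfy category {category!r} for {fid!r}")
        frames.append(
            pd.DataFrame(
                {
                    "panelist_id": [f"p{i:03d}" for i in range(n_panelists)],
                    "factor_id": fid,
                    "round": round,
                    "score": scores,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# CSV round-trip
# --------------------------------------------------------------------------

_DATE_COLS = {"date", "reg_start", "reg_end"}


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the record tables as RFC-4180 CSV with ISO-8601 dates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "patients": dataset.patients,
        "consultations": dataset.consultations,
        "events": dataset.events,
        "prescriptions": dataset.prescriptions,
        "truth_flags": dataset.truth_flags.reset_index(),
    }
    for name, df in tables.items():
        out = df.copy()
        for col in out.columns:
            if col in _DATE_COLS:
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(outdir / f"{name}.csv", index=False)


def read_dataset(indir) -> dict[str, pd.DataFrame]:
    """Read the CSV tables written by :func:`write_dataset` (or any tables
    following the same schema) with parsed dates."""
    indir = Path(indir)
    out: dict[str, pd.DataFrame] = {}
    for name in ("patients", "consultations", "events", "prescriptions"):
        path = indir / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path, dtype={"code": str, "substance_id": str})
        for col in df.columns:
            if col in _DATE_COLS:
                df[col] = pd.to_datetime(df[col])
        if "consultation_id" in df.columns and name in ("events", "prescriptions"):
            df["consultation_id"] = df["consultation_id"].astype("Int64")
        out[name] = df
    return out
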