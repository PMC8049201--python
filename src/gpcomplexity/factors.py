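"""Per-consultation complexity-factor flagging.

Consultation-level factors fire on records coded within the consultation
itself; patient-level factors fire when a qualifying record exists in the
half-open lookback window ``(date - L, date]`` ending at the consultation
date (or any time up to the date, for unbounded "ever" factors). A
consultation is complex when at least one retained factor is present —
the measure is binary, deliberately not a cumulative score.

Boundary semantics (documented, tested):

* an event exactly ``lookback`` days before the consultation is OUTSIDE
  the window; an event on the consultation date is inside;
* flags depend only on records dated on/before the consultation date;
* the frequent-attender count excludes the index consultation itself;
* the first-consultation-after-diagnosis rule selects the chronologically
  first consultation on/after the diagnosis date, same-day included,
  ties broken by lowest consultation id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codesets import CodeSetRegistry, FactorDefinition, chapter_of

__all__ = [
    "FactorFlags",
    "FlagError",
    "flag_consultation_factors",
    "flag_patient_factors",
    "compute_flags",
    "classify_complexity",
]


class FlagError(ValueError):
    """Raised for inconsistent inputs to the flagging engine."""


@dataclass(frozen=True)
class FactorFlags:
    """Boolean factor vector for one consultation."""

    consultation_id: int
    flags: dict[str, bool]

    @property
    def n_factors_present(self) -> int:
        return sum(self.flags.values())


_EMPTY_EVENTS = pd.DataFrame(
    columns=["event_id", "patient_id", "consultation_id", "date", "code"]
)
_EMPTY_RX = pd.DataFrame(
    columns=["rx_id", "patient_id", "consultation_id", "date", "substance_id"]
)


def _normalise(consultations, events, prescriptions):
    cons = consultations.copy()
    if "consultation_id" not in cons.columns:
        raise FlagError("consultations table needs a consultation_id column")
    cons["date"] = pd.to_datetime(cons["date"])
    ev = (events if events is not None and len(events) else _EMPTY_EVENTS).copy()
    rx = (prescriptions if prescriptions is not None and len(prescriptions) else _EMPTY_RX).copy()
    for df in (ev, rx):
        if len(df):
            df["date"] = pd.to_datetime(df["date"])
    # linked records must belong to the consultation's patient and date
    for df, unit in ((ev, "event"), (rx, "prescription")):
        linked = df[df["consultation_id"].notna()]
        if len(linked):
            merged = linked.merge(
                cons[["consultation_id", "patient_id"]],
                on="consultation_id",
                how="left",
                suffixes=("", "_cons"),
            )
            if merged["patient_id_cons"].isna().any():
                raise FlagError(f"{unit}s linked to unknown consultations")
            if (merged["patient_id"] != merged["patient_id_cons"]).any():
                raise FlagError(f"{unit}s linked to a different patient's consultation")
    return cons, ev, rx


def _unit_series(df: pd.DataFrame, definition: FactorDefinition,
                 chapter_map=None, excluded_chapters=()) -> pd.Series:
    value_col = "substance_id" if "substance_id" in df.columns else "code"
    if definition.count_unit == "chapter":
        units = df[value_col].map(lambda c: chapter_of(c, chapter_map))
        if excluded_chapters:
            units = units.where(~units.isin(set(excluded_chapters)))
        return units
    if definition.count_unit == "group":
        groups = definition.code_groups
        return df[value_col].map(lambda c: groups.get(c, c))
    return df[value_col]


def _restrict_codes(df: pd.DataFrame, definition: FactorDefinition) -> pd.DataFrame:
    if not definition.codes:
        return df
    value_col = "substance_id" if "substance_id" in df.columns else "code"
    return df[df[value_col].isin(definition.codes)]


def _source_table(definition, ev, rx):
    return rx if definition.source_domain == "prescriptions" else ev


def flag_consultation_factors(
    registry: CodeSetRegistry,
    consultations: pd.DataFrame,
    events: pd.DataFrame | None = None,
    prescriptions: pd.DataFrame | None = None,
    *,
    chapter_map=None,
    excluded_chapters=(),
) -> pd.DataFrame:
    """Compute consultation-level flags for every consultation.

    Returns a boolean DataFrame indexed by consultation_id with one
    column per consultation-level factor in the registry. A consultation
    with no linked records has every flag False.
    """
    cons, ev, rx = _normalise(consultations, events, prescriptions)
    index = pd.Index(cons["consultation_id"], name="consultation_id")
    defs = registry.factors("consultation")
    flags = pd.DataFrame(False, index=index, columns=[d.factor_id for d in defs])
    for d in defs:
        if d.rule_kind == "code_match":
            src = _source_table(d, ev, rx)
            linked = _restrict_codes(src[src["consultation_id"].notna()], d)
            hit = linked["consultation_id"].unique()
            flags.loc[flags.index.isin(hit), d.factor_id] = True
        elif d.rule_kind in ("count_rule", "percentile_rule"):
            src = _source_table(d, ev, rx)
            linked = _restrict_codes(src[src["consultation_id"].notna()], d).copy()
            if not len(linked):
                continue
            linked["_unit"] = _unit_series(linked, d, chapter_map, excluded_chapters)
            counts = linked.dropna(subset=["_unit"]).groupby("consultation_id")["_unit"].nunique()
            hit = counts.index[counts >= d.count_threshold]
            flags.loc[flags.index.isin(hit), d.factor_id] = True
        elif d.rule_kind == "first_consult_after_dx":
            hit = _first_consults_after(d, cons, ev)
            flags.loc[flags.index.isin(hit), d.factor_id] = True
        else:  # pragma: no cover
            raise FlagError(f"unsupported rule kind {d.rule_kind!r}")
    return flags


def _first_consults_after(definition, cons, ev) -> np.ndarray:
    dx = _restrict_codes(ev, definition)
    if not len(dx):
        return np.array([], dtype=object)
    # tie-break: one representative consultation per (patient, date), the
    # lowest consultation id; then the forward-nearest representative on
    # or after each diagnosis date is the "first consultation".
    reps = (
        cons.sort_values(["patient_id", "date", "consultation_id"])
        .groupby(["patient_id", "date"], as_index=False)
        .first()[["patient_id", "date", "consultation_id"]]
        .sort_values("date", kind="mergesort")
    )
    dx_sorted = dx[["patient_id", "date"]].sort_values("date", kind="mergesort")
    matched = pd.merge_asof(
        dx_sorted,
        reps,
        on="date",
        by="patient_id",
        direction="forward",
        allow_exact_matches=True,
    )
    return matched["consultation_id"].dropna().unique()


def flag_patient_factors(
    registry: CodeSetRegistry,
    consultations: pd.DataFrame,
    events: pd.DataFrame | None = None,
    prescriptions: pd.DataFrame | None = None,
    *,
    exclude_index_consultation: bool = True,
    chapter_map=None,
    excluded_chapters=(),
) -> pd.DataFrame:
    """Compute patient-level flags for every consultation.

    A patient factor applies at a consultation when qualifying history
    exists inside the factor's lookback window ending at the consultation
    date. A consultation dated before all of a patient's history simply
    yields False flags (never an error).
    """
    cons, ev, rx = _normalise(consultations, events, prescriptions)
    index = pd.Index(cons["consultation_id"], name="consultation_id")
    defs = registry.factors("patient")
    flags = pd.DataFrame(False, index=index, columns=[d.factor_id for d in defs])
    base = cons[["consultation_id", "patient_id", "date"]]
    for d in defs:
        if d.source_domain == "consultations":
            hit = _consultation_count_hits(d, base, exclude_index_consultation)
        else:
            src = _restrict_codes(_source_table(d, ev, rx), d)
            if not len(src):
                continue
            value_col = "substance_id" if "substance_id" in src.columns else "code"
            merged = base.merge(
                src[["patient_id", "date", value_col]].rename(
                    columns={"date": "record_date"}
                ),
                on="patient_id",
                how="inner",
            )
            in_window = merged["record_date"] <= merged["date"]
            if not d.is_ever:
                lower = merged["date"] - pd.Timedelta(days=d.lookback_days)
                in_window &= merged["record_date"] > lower
            merged = merged[in_window]
            if d.rule_kind == "code_match":
                hit = merged["consultation_id"].unique()
            elif d.rule_kind in ("count_rule", "percentile_rule"):
                merged = merged.copy()
                merged["_unit"] = _unit_series(merged, d, chapter_map, excluded_chapters)
                counts = merged.dropna(subset=["_unit"]).groupby("consultation_id")["_unit"].nunique()
                hit = counts.index[counts >= d.count_threshold]
            else:
                raise FlagError(
                    f"unsupported patient-level rule kind {d.rule_kind!r}"
                )
        flags.loc[flags.index.isin(hit), d.factor_id] = True
    return flags


def _consultation_count_hits(definition, base, exclude_index):
    """Count-of-consultations rules (frequent attender)."""
    if definition.rule_kind not in ("count_rule", "percentile_rule"):
        raise FlagError(
            f"{definition.factor_id}: consultation-sourced factors must be count rules"
        )
    merged = base.merge(
        base.rename(
            columns={"consultation_id": "other_id", "date": "other_date"}
        ),
        on="patient_id",
        how="inner",
    )
    in_window = merged["other_date"] <= merged["date"]
    if definition.lookback_days is not None:
        lower = merged["date"] - pd.Timedelta(days=definition.lookback_days)
        in_window &= merged["other_date"] > lower
    if exclude_index:
        in_window &= merged["other_id"] != merged["consultation_id"]
    counts = merged[in_window].groupby("consultation_id").size()
    return counts.index[counts >= definition.count_threshold]


def compute_flags(
    registry: CodeSetRegistry,
    consultations: pd.DataFrame,
    events: pd.DataFrame | None = None,
    prescriptions: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Full boolean factor matrix: consultation- and patient-level flags,
    one row per consultation, one column per registry factor."""
    patient_kwargs = dict(kwargs)
    cons_kwargs = {
        k: v for k, v in kwargs.items() if k in ("chapter_map", "excluded_chapters")
    }
    left = flag_consultation_factors(
        registry, consultations, events, prescriptions, **cons_kwargs
    )
    right = flag_patient_factors(
        registry, consultations, events, prescriptions, **patient_kwargs
    )
    return pd.concat([left, right], axis=1)


def classify_complexity(
    flags: pd.DataFrame,
    retained_factors,
    consultations: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    age_bands=None,
) -> pd.DataFrame:
    """Apply the binary measure: complex iff >=1 retained factor present.

    Returns one row per consultation with ``is_complex``,
    ``n_factors_present`` (over retained factors) and
    ``duration_minutes``; when ``patients`` is given, patient sex and the
    age band at consultation (age = consultation year - birth year) are
    attached for stratified reporting.
    """
    retained = list(retained_factors)
    missing = [f for f in retained if f not in flags.columns]
    if missing:
        raise FlagError(f"retained factors absent from flags: {missing}")
    sub = flags[retained] if retained else pd.DataFrame(index=flags.index)
    out = pd.DataFrame(index=flags.index)
    out["n_factors_present"] = sub.sum(axis=1).astype(int) if retained else 0
    out["is_complex"] = out["n_factors_present"] >= 1
    cons = consultations.set_index("consultation_id")
    out["duration_minutes"] = cons["duration_minutes"].reindex(out.index)
    if patients is not None:
        from .report import assign_age_band  # local import to avoid a cycle

        pat = patients.set_index("patient_id")
        pids = cons["patient_id"].reindex(out.index)
        out["sex"] = pat["sex"].reindex(pids).to_numpy()
        years = pd.to_datetime(cons["date"].reindex(out.index)).dt.year
        ages = years.to_numpy() - pat["birth_year"].reindex(pids).to_numpy()
        out["age"] = ages
        out["age_band"] = assign_age_band(ages, age_bands)
    return out.reset_index()
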