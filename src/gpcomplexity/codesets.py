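"""Clinical code sets mapping coded events to complexity factors.

A :class:`FactorDefinition` describes one candidate complexity factor: at
which level it operates (``consultation`` or ``patient``), how it is
triggered (code match, distinct-count rule, or first-consultation-after-
diagnosis rule), over which source records, and — for patient-level
factors — the lookback window within which a coded event activates it.

Code sets are stored as flat CSV, one row per code; rule-only factors
(e.g. pure count rules over all events) carry the sentinel code ``—``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator, Mapping

__all__ = [
    "LEVELS",
    "RULE_KINDS",
    "COUNT_UNITS",
    "SOURCE_DOMAINS",
    "NO_CODE",
    "FactorDefinition",
    "CodeSetRegistry",
    "CodeSetError",
    "chapter_of",
    "load_codesets",
    "write_codesets",
]

LEVELS = ("consultation", "patient")
RULE_KINDS = ("code_match", "count_rule", "first_consult_after_dx", "percentile_rule")
COUNT_UNITS = ("code", "chapter", "group", "substance", "consultation")
SOURCE_DOMAINS = ("events", "prescriptions", "consultations")

#: Sentinel written to the ``code`` column for factors with no code list.
NO_CODE = "—"


class CodeSetError(ValueError):
    """Raised for malformed code-set files or invalid factor definitions."""


def chapter_of(code: str, chapter_map: Mapping[str, str] | None = None) -> str:
    """Return the chapter of a clinical code.

    By default the chapter is the code's first character, case preserved
    (the standard Read v2 convention). Pass ``chapter_map`` to override
    individual codes for other terminologies.
    """
    if not code:
        raise CodeSetError("empty code string has no chapter")
    if chapter_map is not None and code in chapter_map:
        return chapter_map[code]
    return code[0]


@dataclass(frozen=True)
class FactorDefinition:
    """One candidate complexity factor and its trigger rule.

    Parameters
    ----------
    factor_id:
        Stable identifier used throughout the pipeline.
    label:
        Human-readable wording.
    level:
        ``"consultation"`` (the topic is coded within the consultation) or
        ``"patient"`` (an enduring characteristic evaluated over a lookback
        window ending at the consultation date).
    rule_kind:
        ``code_match`` — true iff any in-scope record's code is in ``codes``.
        ``count_rule`` / ``percentile_rule`` — true iff the number of
        distinct ``count_unit`` values among in-scope records reaches
        ``count_threshold``; ``percentile_rule`` marks thresholds that are
        re-specified from an empirical percentile of per-patient counts.
        ``first_consult_after_dx`` — true for the chronologically first
        consultation on/after a matching diagnosis code.
    codes:
        Code list. For count rules an empty code list means "count all
        in-scope records"; a non-empty list restricts counting to matching
        codes (or substance ids, for prescription rules).
    lookback_days:
        Window length in days for patient-level factors; ``None`` means
        unbounded ("ever"). Consultation-level rules have no lookback (the
        window is the consultation itself).
    count_unit:
        What is counted as distinct by count rules: ``code``, ``chapter``,
        ``group`` (via ``code_groups``), ``substance``, or ``consultation``.
    code_groups:
        Optional map code -> group id, used when ``count_unit == "group"``
        (e.g. grouping condition codes into long-term conditions).
    percentile:
        For ``percentile_rule`` factors, the percentile (in (0, 1)) from
        which ``count_threshold`` was or should be derived.
    """

    factor_id: str
    label: str
    level: str
    rule_kind: str
    codes: frozenset[str] = frozenset()
    lookback_days: int | None = None
    count_threshold: int | None = None
    count_unit: str | None = None
    source_domain: str = "events"
    code_groups: Mapping[str, str] = field(default_factory=dict)
    percentile: float | None = None

    def __post_init__(self) -> None:
        if not self.factor_id:
            raise CodeSetError("factor_id must be non-empty")
        if self.level not in LEVELS:
            raise CodeSetError(f"{self.factor_id}: unknown level {self.level!r}")
        if self.rule_kind not in RULE_KINDS:
            raise CodeSetError(f"{self.factor_id}: unknown rule_kind {self.rule_kind!r}")
        if self.source_domain not in SOURCE_DOMAINS:
            raise CodeSetError(
                f"{self.factor_id}: unknown source_domain {self.source_domain!r}"
            )
        object.__setattr__(self, "codes", frozenset(self.codes))
        if self.rule_kind in ("code_match", "first_consult_after_dx") and not self.codes:
            raise CodeSetError(f"{self.factor_id}: {self.rule_kind} requires codes")
        if self.rule_kind in ("count_rule", "percentile_rule"):
            if self.count_threshold is None or self.count_threshold < 1:
                raise CodeSetError(
                    f"{self.factor_id}: {self.rule_kind} requires count_threshold >= 1"
                )
            if self.count_unit not in COUNT_UNITS:
                raise CodeSetError(
                    f"{self.factor_id}: count rule requires a valid count_unit, "
                    f"got {self.count_unit!r}"
                )
        if self.level == "consultation" and self.rule_kind == "code_match" and (
            self.lookback_days is not None
        ):
            raise CodeSetError(
                f"{self.factor_id}: consultation-level code_match rules have no "
                "lookback (the window is the consultation itself)"
            )
        if self.lookback_days is not None and self.lookback_days <= 0:
            raise CodeSetError(f"{self.factor_id}: lookback_days must be positive")
        if self.percentile is not None and not (0.0 < self.percentile < 1.0):
            raise CodeSetError(f"{self.factor_id}: percentile must lie in (0, 1)")

    @property
    def is_ever(self) -> bool:
        """True when the lookback window is unbounded."""
        return self.lookback_days is None

    def with_codes(self, extra: Iterable[str]) -> "FactorDefinition":
        return replace(self, codes=self.codes | frozenset(extra))


class CodeSetRegistry:
    """Ordered collection of :class:`FactorDefinition` keyed by factor_id."""

    def __init__(self, definitions: Iterable[FactorDefinition] = ()) -> None:
        self._defs: dict[str, FactorDefinition] = {}
        for d in definitions:
            self.add(d)

    def add(self, definition: FactorDefinition) -> None:
        existing = self._defs.get(definition.factor_id)
        if existing is None:
            self._defs[definition.factor_id] = definition
            return
        # Same factor listed again: union the code lists, but every other
        # attribute must agree.
        for f in fields(existing):
            if f.name in ("codes", "code_groups"):
                continue
            if getattr(existing, f.name) != getattr(definition, f.name):
                raise CodeSetError(
                    f"conflicting definitions for factor {definition.factor_id!r} "
                    f"({f.name!r} differs)"
                )
        merged_groups = dict(existing.code_groups)
        merged_groups.update(definition.code_groups)
        self._defs[definition.factor_id] = replace(
            existing,
            codes=existing.codes | definition.codes,
            code_groups=merged_groups,
        )

    def remove(self, factor_id: str) -> None:
        del self._defs[factor_id]

    def replace_definition(self, definition: FactorDefinition) -> None:
        self._defs[definition.factor_id] = definition

    def __getitem__(self, factor_id: str) -> FactorDefinition:
        return self._defs[factor_id]

    def __contains__(self, factor_id: str) -> bool:
        return factor_id in self._defs

    def __iter__(self) -> Iterator[FactorDefinition]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodeSetRegistry):
            return NotImplemented
        return self._defs == other._defs

    def factor_ids(self, level: str | None = None) -> list[str]:
        return [d.factor_id for d in self.factors(level)]

    def factors(self, level: str | None = None) -> list[FactorDefinition]:
        if level is None:
            return list(self._defs.values())
        if level not in LEVELS:
            raise CodeSetError(f"unknown level {level!r}")
        return [d for d in self._defs.values() if d.level == level]

    def subset(self, factor_ids: Iterable[str]) -> "CodeSetRegistry":
        keep = list(factor_ids)
        missing = [f for f in keep if f not in self._defs]
        if missing:
            raise CodeSetError(f"unknown factor ids: {missing}")
        return CodeSetRegistry(self._defs[f] for f in keep)

    def copy(self) -> "CodeSetRegistry":
        return CodeSetRegistry(self._defs.values())


_COLUMNS = [
    "factor_id",
    "label",
    "level",
    "rule_kind",
    "lookback",
    "count_threshold",
    "count_unit",
    "source_domain",
    "percentile",
    "code",
    "code_group",
]


def _parse_lookback(raw: str, row: int) -> int | None:
    raw = raw.strip()
    if raw == "" or raw.lower() == "ever":
        return None
    try:
        return int(raw)
    except ValueError:
        raise CodeSetError(f"row {row}: invalid lookback {raw!r}") from None


def load_codesets(path) -> CodeSetRegistry:
    """Load a code-set CSV into a :class:`CodeSetRegistry`.

    One row per (factor, code); duplicate codes within a factor are
    deduplicated, repeated factor rows are merged. Validation errors are
    reported with the offending row number.
    """
    registry = CodeSetRegistry()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CodeSetError(f"{path}: empty file")
        missing = {"factor_id", "level", "rule_kind", "code"} - set(reader.fieldnames)
        if missing:
            raise CodeSetError(f"{path}: missing columns {sorted(missing)}")
        n_rows = 0
        for row_no, row in enumerate(reader, start=2):
            n_rows += 1
            code = (row.get("code") or "").strip()
            codes = frozenset() if code in ("", NO_CODE) else frozenset([code])
            group = (row.get("code_group") or "").strip()
            code_groups = {code: group} if group and codes else {}
            threshold_raw = (row.get("count_threshold") or "").strip()
            percentile_raw = (row.get("percentile") or "").strip()
            try:
                definition = FactorDefinition(
                    factor_id=(row.get("factor_id") or "").strip(),
                    label=(row.get("label") or "").strip(),
                    level=(row.get("level") or "").strip(),
                    rule_kind=(row.get("rule_kind") or "").strip(),
                    codes=codes,
                    lookback_days=_parse_lookback(row.get("lookback") or "", row_no),
                    count_threshold=int(threshold_raw) if threshold_raw else None,
                    count_unit=(row.get("count_unit") or "").strip() or None,
                    source_domain=(row.get("source_domain") or "events").strip(),
                    code_groups=code_groups,
                    percentile=float(percentile_raw) if percentile_raw else None,
                )
            except CodeSetError as exc:
                raise CodeSetError(f"row {row_no}: {exc}") from None
            try:
                registry.add(definition)
            except CodeSetError as exc:
                raise CodeSetError(f"row {row_no}: {exc}") from None
        if n_rows == 0:
            raise CodeSetError(f"{path}: no code rows")
    return registry


def write_codesets(registry: CodeSetRegistry, path) -> None:
    """Write a registry back to the flat CSV format (round-trips with
    :func:`load_codesets`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for d in registry:
            if d.lookback_days is not None:
                lookback = str(d.lookback_days)
            else:
                lookback = "" if d.level == "consultation" else "ever"
            common = [
                d.factor_id,
                d.label,
                d.level,
                d.rule_kind,
                lookback,
                "" if d.count_threshold is None else str(d.count_threshold),
                d.count_unit or "",
                d.source_domain,
                "" if d.percentile is None else repr(d.percentile),
            ]
            if d.codes:
                for code in sorted(d.codes):
                    writer.writerow(common + [code, d.code_groups.get(code, "")])
            else:
                writer.writerow(common + [NO_CODE, ""])
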