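"""Two-round Delphi consensus aggregation.

Panelists score each candidate factor on a 1–5 scale. Scores of 3–5 count
as endorsement, a score of 1 as rejection. A factor is accepted when
strictly more than 70% of its voters endorse it and strictly fewer than
20% reject it; it is not accepted when fewer than 40% endorse and more
than 20% reject; anything else is uncertain. Round-1 uncertain factors
(and newly suggested factors) are voted on again in round 2 under the
same thresholds, and factors still uncertain after round 2 are rejected.

Conventions (documented, configurable via :class:`DelphiThresholds`):

* all four threshold comparisons are strict, exactly as stated;
* a score of 2 counts toward neither endorsement nor rejection but stays
  in the denominator;
* abstentions (missing votes) are excluded from the denominator;
* the median of an even panel is the mean of the two central scores, and
  the IQR uses the inclusive (linear-interpolation) quartile convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STATUSES",
    "PanelVote",
    "DelphiThresholds",
    "RoundOutcome",
    "DelphiError",
    "classify_factor",
    "classify_round",
    "run_two_rounds",
    "feedback_report",
    "votes_for_outcome",
]

STATUSES = ("endorsed", "rejected", "uncertain")

VOTE_COLUMNS = ["panelist_id", "factor_id", "round", "score"]


class DelphiError(ValueError):
    """Raised for malformed vote tables or workflow violations."""


@dataclass(frozen=True)
class PanelVote:
    """One panelist's score for one factor in one round."""

    panelist_id: str
    factor_id: str
    round: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise DelphiError(f"score must be in 1..5, got {self.score}")
        if self.round not in (1, 2):
            raise DelphiError(f"round must be 1 or 2, got {self.round}")


@dataclass(frozen=True)
class DelphiThresholds:
    """Endorsement/rejection rules; defaults follow the published wording."""

    endorse_min_prop: float = 0.70
    reject_max_prop_for_accept: float = 0.20
    endorse_max_prop_for_reject: float = 0.40
    reject_min_prop_for_reject: float = 0.20
    endorse_scores: frozenset[int] = frozenset({3, 4, 5})
    reject_scores: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        for name in (
            "endorse_min_prop",
            "reject_max_prop_for_accept",
            "endorse_max_prop_for_reject",
            "reject_min_prop_for_reject",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DelphiError(f"{name} must lie in [0, 1], got {v}")
        if set(self.endorse_scores) & set(self.reject_scores):
            raise DelphiError("endorse_scores and reject_scores must be disjoint")


@dataclass(frozen=True)
class RoundOutcome:
    """Per-factor classification for a single round."""

    factor_id: str
    round: int
    n_votes: int
    prop_endorse: float
    prop_reject: float
    median_score: float
    iqr: tuple[float, float]
    status: str


def _as_votes_frame(votes) -> pd.DataFrame:
    if isinstance(votes, pd.DataFrame):
        df = votes
    else:
        df = pd.DataFrame([
            v.__dict__ if isinstance(v, PanelVote) else v for v in votes
        ])
    if df.empty:
        raise DelphiError("empty vote table")
    missing = set(VOTE_COLUMNS) - set(df.columns)
    if missing:
        raise DelphiError(f"vote table missing columns {sorted(missing)}")
    df = df.loc[df["score"].notna(), VOTE_COLUMNS].copy()
    if df.empty:
        raise DelphiError("vote table contains no scored votes")
    df["score"] = df["score"].astype(int)
    df["round"] = df["round"].astype(int)
    if not df["score"].isin([1, 2, 3, 4, 5]).all():
        bad = sorted(df.loc[~df["score"].isin([1, 2, 3, 4, 5]), "score"].unique())
        raise DelphiError(f"scores outside 1..5: {bad}")
    dup = df.duplicated(["panelist_id", "factor_id", "round"])
    if dup.any():
        raise DelphiError(
            "duplicate (panelist, factor, round) votes: "
            f"{df.loc[dup, ['panelist_id', 'factor_id']].to_records(index=False)[:5]}"
        )
    return df


def classify_factor(
    votes, thresholds: DelphiThresholds | None = None
) -> RoundOutcome:
    """Classify one factor for one round from its votes.

    ``votes`` may be a DataFrame or an iterable of :class:`PanelVote`; all
    votes must refer to the same factor and round. Abstentions should
    simply be absent from the table (they do not enter the denominator).
    """
    thresholds = thresholds or DelphiThresholds()
    df = _as_votes_frame(votes)
    factor_ids = df["factor_id"].unique()
    rounds = df["round"].unique()
    if len(factor_ids) != 1 or len(rounds) != 1:
        raise DelphiError(
            f"classify_factor expects one factor and one round, got factors "
            f"{sorted(map(str, factor_ids))} rounds {sorted(map(int, rounds))}"
        )
    scores = df["score"].to_numpy()
    n = len(scores)
    prop_endorse = float(np.isin(scores, list(thresholds.endorse_scores)).mean())
    prop_reject = float(np.isin(scores, list(thresholds.reject_scores)).mean())
    if (
        prop_endorse > thresholds.endorse_min_prop
        and prop_reject < thresholds.reject_max_prop_for_accept
    ):
        status = "endorsed"
    elif (
        prop_endorse < thresholds.endorse_max_prop_for_reject
        and prop_reject > thresholds.reject_min_prop_for_reject
    ):
        status = "rejected"
    else:
        status = "uncertain"
    q1, q3 = np.percentile(scores, [25, 75])  # inclusive/linear quartiles
    return RoundOutcome(
        factor_id=str(factor_ids[0]),
        round=int(rounds[0]),
        n_votes=n,
        prop_endorse=prop_endorse,
        prop_reject=prop_reject,
        median_score=float(np.median(scores)),
        iqr=(float(q1), float(q3)),
        status=status,
    )


def classify_round(
    votes, thresholds: DelphiThresholds | None = None
) -> pd.DataFrame:
    """Classify every factor present in a single-round vote table.

    Returns one row per factor: n_votes, prop_endorse, prop_reject,
    median_score, iqr_low, iqr_high, status. Classification is invariant
    to vote order and panelist relabelling.
    """
    df = _as_votes_frame(votes)
    rows = []
    for factor_id, sub in df.groupby("factor_id", sort=True):
        out = classify_factor(sub, thresholds)
        rows.append(
            {
                "factor_id": factor_id,
                "round": out.round,
                "n_votes": out.n_votes,
                "prop_endorse": out.prop_endorse,
                "prop_reject": out.prop_reject,
                "median_score": out.median_score,
                "iqr_low": out.iqr[0],
                "iqr_high": out.iqr[1],
                "status": out.status,
            }
        )
    return pd.DataFrame(rows)


def run_two_rounds(
    round1_votes,
    round2_votes=None,
    round2_new_factors=(),
    thresholds: DelphiThresholds | None = None,
) -> pd.DataFrame:
    """Run the full two-round workflow and return final per-factor statuses.

    Round-1 endorsed/rejected decisions are final. Round-1 uncertain
    factors and ``round2_new_factors`` take their round-2 classification;
    any factor still uncertain after round 2 is rejected. Round-2 votes
    for a factor already finalised in round 1 are an error.

    Returns a DataFrame with columns factor_id, round1_status,
    round2_status, final_status, decided_in_round, median_r1, median_r2.
    """
    r1 = classify_round(round1_votes, thresholds).set_index("factor_id")
    new_factors = set(map(str, round2_new_factors))
    overlap = new_factors & set(r1.index)
    if overlap:
        raise DelphiError(f"round-2 'new' factors already voted in round 1: {sorted(overlap)}")

    if round2_votes is not None and len(round2_votes):
        r2 = classify_round(round2_votes, thresholds).set_index("factor_id")
    else:
        r2 = pd.DataFrame(
            columns=["n_votes", "prop_endorse", "prop_reject", "median_score",
                     "iqr_low", "iqr_high", "status"]
        )
    eligible = set(r1.index[r1["status"] == "uncertain"]) | new_factors
    finalised = set(r2.index) - eligible
    if finalised:
        raise DelphiError(
            f"round-2 votes for factors already finalised in round 1: {sorted(finalised)}"
        )

    rows = []
    for factor_id in sorted(set(r1.index) | set(r2.index) | new_factors):
        r1_status = r1.loc[factor_id, "status"] if factor_id in r1.index else None
        r2_status = r2.loc[factor_id, "status"] if factor_id in r2.index else None
        if r1_status in ("endorsed", "rejected"):
            final, decided = r1_status, 1
        elif r2_status in ("endorsed", "rejected"):
            final, decided = r2_status, 2
        else:
            # uncertain after round 2 (or never voted on in round 2)
            final, decided = "rejected", 2
        rows.append(
            {
                "factor_id": factor_id,
                "round1_status": r1_status,
                "round2_status": r2_status,
                "final_status": final,
                "decided_in_round": decided,
                "median_r1": r1.loc[factor_id, "median_score"] if factor_id in r1.index else np.nan,
                "median_r2": r2.loc[factor_id, "median_score"] if factor_id in r2.index else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeedbackReport:
    """Individualised round feedback for one panelist."""

    panelist_id: str
    rows: pd.DataFrame = field(repr=False)
    summary: dict = field(default_factory=dict)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"Feedback report for panelist {self.panelist_id}\n")
        buf.write(
            f"Factors scored: {self.summary['n_factors']}; "
            f"mean |own - panel median|: {self.summary['mean_abs_deviation']:.2f}; "
            f"scores within panel IQR: {self.summary['n_within_iqr']}"
            f"/{self.summary['n_factors']}\n\n"
        )
        buf.write(self.rows.to_string(index=False))
        buf.write("\n")
        return buf.getvalue()


def feedback_report(
    round1_votes, panelist_id, thresholds: DelphiThresholds | None = None
) -> FeedbackReport:
    """Build the individualised feedback report sent between rounds.

    For each factor the panelist scored: own score, the panel median and
    IQR, and the deviation from the median. Rows are ordered by
    factor_id; an overall summary covers all scored factors.
    """
    df = _as_votes_frame(round1_votes)
    own = df[df["panelist_id"] == panelist_id]
    if own.empty:
        raise DelphiError(f"unknown panelist {panelist_id!r}")
    outcomes = classify_round(df, thresholds).set_index("factor_id")
    rows = []
    for _, vote in own.sort_values("factor_id").iterrows():
        out = outcomes.loc[vote["factor_id"]]
        rows.append(
            {
                "factor_id": vote["factor_id"],
                "own_score": int(vote["score"]),
                "panel_median": float(out["median_score"]),
                "iqr_low": float(out["iqr_low"]),
                "iqr_high": float(out["iqr_high"]),
                "deviation": float(vote["score"] - out["median_score"]),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_factors": len(table),
        "mean_abs_deviation": float(table["deviation"].abs().mean()),
        "n_within_iqr": int(
            ((table["own_score"] >= table["iqr_low"])
             & (table["own_score"] <= table["iqr_high"])).sum()
        ),
    }
    return FeedbackReport(panelist_id=str(panelist_id), rows=table, summary=summary)


# Deterministic score patterns guaranteed to classify as the named status
# under the default thresholds, for any panel size >= 1.
_STATUS_PATTERNS = {
    "endorsed": (3, 4, 5, 4),   # prop_endorse = 1.0 > 0.70, prop_reject = 0.0
    "rejected": (1, 1, 2),      # prop_endorse = 0.0 < 0.40, prop_reject >= 2/3
    "uncertain": (2, 3),        # straddles both rules at every n
}


def votes_for_outcome(
    status: str, n_panelists: int, factor_id: str, round: int = 1,
    panelist_prefix: str = "p",
) -> pd.DataFrame:
    """Construct a deterministic vote table classifying as ``status``.

    Used to replay recorded per-round statuses through the vote-level
    workflow. Guaranteed for any ``n_panelists >= 1`` under the default
    thresholds.
    """
    if status not in STATUSES:
        raise DelphiError(f"unknown status {status!r}")
    if n_panelists < 1:
        raise DelphiError("n_panelists must be >= 1")
    pattern = _STATUS_PATTERNS[status]
    return pd.DataFrame(
        {
            "panelist_id": [f"{panelist_prefix}{i:03d}" for i in range(n_panelists)],
            "factor_id": factor_id,
            "round": round,
            "score": [pattern[i % len(pattern)] for i in range(n_panelists)],
        }
    )
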