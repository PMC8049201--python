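"""Summary surfaces for an applied complexity measure.

Given per-consultation complexity results, computes the proportion of
complex consultations, mean durations of complex vs non-complex
consultations with a large-sample (Welch) normal interval on the
difference, and age–sex stratified complexity proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_AGE_BAND_EDGES",
    "ComplexitySummary",
    "assign_age_band",
    "summarise",
    "plot_strata",
]

# 0-4, 5-14, then 10-year bands to >=85
DEFAULT_AGE_BAND_EDGES = (0, 5, 15, 25, 35, 45, 55, 65, 75, 85)


def _band_labels(edges) -> list[str]:
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


def assign_age_band(ages, edges=None) -> pd.Categorical:
    """Map ages to configurable bands (default 0-4, 5-14, ..., 75-84, 85+)."""
    edges = tuple(edges) if edges is not None else DEFAULT_AGE_BAND_EDGES
    labels = _band_labels(edges)
    bins = list(edges) + [np.inf]
    return pd.cut(np.asarray(ages, dtype=float), bins=bins, labels=labels,
                  right=False, include_lowest=True)


@dataclass(frozen=True)
class ComplexitySummary:
    """Headline statistics for one scored dataset."""

    n_consultations: int
    n_complex: int
    prop_complex: float
    mean_duration_complex: float | None
    mean_duration_noncomplex: float | None
    difference: float | None
    difference_ci: tuple[float, float] | None
    n_missing_duration: int
    strata: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "n_consultations": self.n_consultations,
            "n_complex": self.n_complex,
            "prop_complex": self.prop_complex,
            "mean_duration_complex": self.mean_duration_complex,
            "mean_duration_noncomplex": self.mean_duration_noncomplex,
            "difference": self.difference,
            "difference_ci": list(self.difference_ci) if self.difference_ci else None,
            "n_missing_duration": self.n_missing_duration,
        }


def summarise(
    results: pd.DataFrame, confidence: float = 0.95
) -> ComplexitySummary:
    """Summarise per-consultation complexity results.

    ``results`` needs ``is_complex`` and ``duration_minutes`` columns;
    ``age_band`` and ``sex`` add the stratified table. Consultations with
    missing duration stay in the complexity denominator and are counted
    separately. With no complex (or no non-complex) consultations the
    difference and its CI are reported as undefined (``None``) rather
    than raising.
    """
    if "is_complex" not in results.columns:
        raise ValueError("results must have an is_complex column")
    n = len(results)
    if n == 0:
        raise ValueError("empty results table")
    is_complex = results["is_complex"].astype(bool)
    n_complex = int(is_complex.sum())
    dur = pd.to_numeric(results["duration_minutes"], errors="coerce")
    n_missing = int(dur.isna().sum())
    dc = dur[is_complex].dropna()
    dn = dur[~is_complex].dropna()

    mean_c = float(dc.mean()) if len(dc) else None
    mean_n = float(dn.mean()) if len(dn) else None
    difference = mean_c - mean_n if (mean_c is not None and mean_n is not None) else None
    ci = None
    if difference is not None and len(dc) > 1 and len(dn) > 1:
        # Welch-style large-sample normal interval on the mean difference
        se = float(np.sqrt(dc.var(ddof=1) / len(dc) + dn.var(ddof=1) / len(dn)))
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        ci = (difference - z * se, difference + z * se)

    strata = pd.DataFrame(columns=["age_band", "sex", "n", "n_complex", "prop_complex"])
    if {"age_band", "sex"} <= set(results.columns):
        grouped = (
            results.assign(is_complex=is_complex)
            .groupby(["age_band", "sex"], observed=False)["is_complex"]
            .agg(n="size", n_complex="sum")
            .reset_index()
        )
        grouped = grouped[grouped["n"] > 0].reset_index(drop=True)
        grouped["prop_complex"] = grouped["n_complex"] / grouped["n"]
        strata = grouped

    return ComplexitySummary(
        n_consultations=n,
        n_complex=n_complex,
        prop_complex=n_complex / n,
        mean_duration_complex=mean_c,
        mean_duration_noncomplex=mean_n,
        difference=difference,
        difference_ci=ci,
        n_missing_duration=n_missing,
        strata=strata,
    )


def plot_strata(summary: ComplexitySummary, ax=None):
    """Bar chart of complexity proportion by age band and sex."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    strata = summary.strata
    if strata.empty:
        raise ValueError("summary has no strata to plot")
    bands = list(strata["age_band"].unique())
    sexes = sorted(strata["sex"].unique())
    width = 0.8 / max(len(sexes), 1)
    x = np.arange(len(bands))
    for i, sex in enumerate(sexes):
        sub = strata[strata["sex"] == sex].set_index("age_band")["prop_complex"]
        ax.bar(x + i * width, sub.reindex(bands).to_numpy(), width, label=str(sex))
    ax.set_xticks(x + width * (len(sexes) - 1) / 2)
    ax.set_xticklabels(bands, rotation=45, ha="right")
    ax.set_ylabel("Proportion complex")
    ax.set_xlabel("Age band")
    ax.legend(title="Sex")
    ax.figure.tight_layout()
    return ax
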