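"""Group-level descriptive statistics and significance tests.

Per compound group (launched / clinical / preclinical / tool / reference)
this module reports medians and means of the normalized survival cells and
of the finite-difference derivatives, and wraps the significance tests
applied to them: Mood's median test for pairwise median differences, the
two-sample Kolmogorov-Smirnov test for distribution differences, and
one-way ANOVA with Tukey's post-hoc for mean comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cassette import ValidationError
from .survival import (
    STANDARD_CELLS,
    STANDARD_CONCENTRATIONS_M,
    STANDARD_TEMPERATURES_C,
    DerivativeSet,
    SurvivalSurface,
)


class DegenerateTableError(ValidationError):
    """Mood's test contingency table is degenerate (all values tied)."""


@dataclass
class GroupSummary:
    """Median and mean of every observable for one compound group.

    ``sn_median``/``sn_mean`` map (C, T) cells; ``dc_*`` map temperature;
    ``dt_*`` map concentration.  Median and mean of a cell are always
    computed from the same compound subset (listwise per cell); ``n`` maps
    each cell to the number of compounds that contributed.
    """

    group: str
    n_compounds: int
    sn_median: dict = field(default_factory=dict)
    sn_mean: dict = field(default_factory=dict)
    dc_median: dict = field(default_factory=dict)
    dc_mean: dict = field(default_factory=dict)
    dt_median: dict = field(default_factory=dict)
    dt_mean: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)


def summarize_group(
    members: Sequence[tuple[SurvivalSurface, DerivativeSet]], group: str = ""
) -> GroupSummary:
    """Medians and means of all 11 observables over one group's compounds."""
    members = list(members)
    if not members:
        raise ValidationError("summarize_group: empty group")
    summary = GroupSummary(group=group, n_compounds=len(members))
    for cell in STANDARD_CELLS:
        values = [s.sn[cell] for s, _ in members if cell in s.sn]
        summary.n[("sn", cell)] = len(values)
        if values:
            summary.sn_median[cell] = float(np.median(values))
            summary.sn_mean[cell] = float(np.mean(values))
    for t in STANDARD_TEMPERATURES_C:
        values = [d.dc[t] for _, d in members if t in d.dc]
        summary.n[("dc", t)] = len(values)
        if values:
            summary.dc_median[t] = float(np.median(values))
            summary.dc_mean[t] = float(np.mean(values))
    for c in STANDARD_CONCENTRATIONS_M:
        values = [d.dt[c] for _, d in members if c in d.dt]
        summary.n[("dt", c)] = len(values)
        if values:
            summary.dt_median[c] = float(np.median(values))
            summary.dt_mean[c] = float(np.mean(values))
    return summary


def summary_table(summaries: Sequence[GroupSummary]):
    """Tidy table of group medians/means: one row per group x observable."""
    import pandas as pd

    rows = []
    for s in summaries:
        for cell in STANDARD_CELLS:
            if cell in s.sn_median:
                rows.append(
                    {
                        "group": s.group,
                        "observable": "sn",
                        "conc_uM": cell[0] * 1e6,
                        "temp_C": cell[1],
                        "median": s.sn_median[cell],
                        "mean": s.sn_mean[cell],
                        "n": s.n[("sn", cell)],
                    }
                )
        for t in STANDARD_TEMPERATURES_C:
            if t in s.dc_median:
                rows.append(
                    {
                        "group": s.group,
                        "observable": "dc",
                        "conc_uM": float("nan"),
                        "temp_C": t,
                        "median": s.dc_median[t],
                        "mean": s.dc_mean[t],
                        "n": s.n[("dc", t)],
                    }
                )
        for c in STANDARD_CONCENTRATIONS_M:
            if c in s.dt_median:
                rows.append(
                    {
                        "group": s.group,
                        "observable": "dt",
                        "conc_uM": c * 1e6,
                        "temp_C": float("nan"),
                        "median": s.dt_median[c],
                        "mean": s.dt_mean[c],
                        "n": s.n[("dt", c)],
                    }
                )
    return pd.DataFrame(rows)


def mood_median_test(
    a: Sequence[float],
    b: Sequence[float],
    correction: bool = False,
    exact: bool = False,
) -> tuple[float, float]:
    """Mood's median test for a difference between two sample medians.

    Counts, per sample, the values above versus not-above the pooled grand
    median (ties with the grand median fall in the "not above" row), and
    tests the resulting 2x2 table with a 1-df chi-square.  No continuity
    correction by default; ``correction=True`` applies Yates' correction.

    ``exact=True`` replaces the chi-square p-value with the two-sided
    hypergeometric (Fisher) probability of the table.  Because the pooled
    values -- and hence the grand median -- are fixed under relabelling,
    this equals the exact permutation test of group labels, and is the
    appropriate choice for small samples where the 1-df chi-square
    approximation is anticonservative.

    Returns ``(statistic, p_value)``; the statistic is always the
    (uncorrected or corrected) chi-square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mood_median_test: both samples must be non-empty")
    grand = np.median(np.concatenate([a, b]))
    if np.all(a == grand) and np.all(b == grand):
        raise DegenerateTableError("all values equal the grand median")
    try:
        stat, p, _, table = stats.median_test(
            a, b, ties="below", correction=correction
        )
    except ValueError as exc:
        raise DegenerateTableError(str(exc)) from exc
    if exact:
        p = stats.fisher_exact(table)[1]
    return float(stat), float(p)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (two-sided); returns (D, p)."""
    result = stats.ks_2samp(a, b)
    return float(result.statistic), float(result.pvalue)


def anova_tukey(groups: Mapping[str, Sequence[float]]):
    """One-way ANOVA followed by Tukey's HSD pairwise comparisons.

    Returns ``(f_statistic, p_value, pairwise)`` where ``pairwise`` is a
    tidy table with one row per group pair.
    """
    import pandas as pd

    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 2:
        raise ValidationError("anova_tukey: need at least 2 groups")
    for label, sample in zip(labels, samples):
        if sample.size < 2:
            raise ValidationError(f"anova_tukey: group {label!r} has fewer than 2 values")
    f_stat, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_difference": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_value": float(tukey.pvalue[i, j]),
                }
            )
    return float(f_stat), float(p), pd.DataFrame(rows)


def pairwise_tests(values_by_group: Mapping[str, Sequence[float]], observable: str = ""):
    """All pairwise Mood and K-S tests between groups, as a tidy table."""
    import pandas as pd

    labels = list(values_by_group)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = values_by_group[labels[i]]
            b = values_by_group[labels[j]]
            try:
                mood_stat, mood_p = mood_median_test(a, b)
            except (DegenerateTableError, ValidationError):
                mood_stat, mood_p = float("nan"), float("nan")
            ks_stat, ks_p = ks_two_sample(a, b)
            rows.append(
                {
                    "observable": observable,
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mood_statistic": mood_stat,
                    "mood_p": mood_p,
                    "ks_statistic": ks_stat,
                    "ks_p": ks_p,
                }
            )
    return pd.DataFrame(rows)
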