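"""Median-touchstone scoring and druglikeness classification.

Every test compound is compared, condition by condition, against the
*touchstones*: the per-condition medians of a reference pool of approved
drugs.  Eleven touchstones exist for the standard design -- six normalized
survival medians Sn(C, T), two concentration-derivative medians (one per
heat-shock temperature) and three temperature-derivative medians (one per
concentration).

Binary indicators:

* ``phi(C, T) = 1`` iff the compound's Sn(C, T) is at or above the
  reference median (ties score 1);
* ``chi = 1`` iff a derivative is strictly above its reference median
  (ties score 0).

The tie directions are deliberately asymmetric: a compound matching the
reference median survival is counted with the upper half, while a
derivative matching the median is counted with the stable (lower) half.

Aggregates count touchstone crossings:

* ``Phi(T)`` = sum of phi over the three concentrations at fixed T (0-3);
* ``Theta(C)`` = sum of phi over the two temperatures at fixed C (0-2);
* ``Phi(dT)`` = sum of chi over the three temperature derivatives (0-3);
* ``Theta(dC)`` = sum of chi over the two concentration derivatives (0-2);
* ``Psi_survival`` = sum of all six phi bits (0-6), which equals both the
  sum of Phi(T) over temperatures and the sum of Theta(C) over
  concentrations;
* ``Psi_derivative`` = Phi(dT) + Theta(dC) (0-5).

Within a compound group, ``Gamma`` converts scores into percentages: the
percentage of compounds attaining a given value (or value interval) of an
observable.  Druglikeness is called from interval membership on the two
Psi axes: survival high = 4-6, derivative high = 0-2 (low variation of
survival across conditions indicates robust protection, so *low*
derivative crossing counts are favourable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cassette import ValidationError
from .survival import (
    STANDARD_CELLS,
    STANDARD_CONCENTRATIONS_M,
    STANDARD_TEMPERATURES_C,
    DerivativeSet,
    SurvivalSurface,
)

logger = logging.getLogger(__name__)

PSI_SURVIVAL_RANGE = range(0, 7)
PSI_DERIVATIVE_RANGE = range(0, 6)
#: druglikeness intervals on the Psi axes: (low, high) inclusive bounds
SURVIVAL_HIGH_INTERVAL = (4, 6)
SURVIVAL_LOW_INTERVAL = (0, 3)
DERIVATIVE_HIGH_INTERVAL = (0, 2)
DERIVATIVE_LOW_INTERVAL = (3, 5)


@dataclass(frozen=True)
class ReferenceTouchstones:
    """The 11 reference-pool medians every compound is binarized against."""

    sn_median: Mapping[tuple[float, float], float]
    dc_median: Mapping[float, float]
    dt_median: Mapping[float, float]
    n_reference: int

    def __post_init__(self) -> None:
        missing = [cell for cell in STANDARD_CELLS if cell not in self.sn_median]
        missing += [t for t in STANDARD_TEMPERATURES_C if t not in self.dc_median]
        missing += [c for c in STANDARD_CONCENTRATIONS_M if c not in self.dt_median]
        if missing:
            raise ValidationError(f"touchstones missing cells: {missing}")


def median(values: Sequence[float]) -> float:
    """Median with the usual convention: odd n -> middle order statistic,
    even n -> mean of the two middle order statistics."""
    if len(values) == 0:
        raise ValidationError("median of empty collection")
    return float(np.median(np.asarray(values, dtype=float)))


def compute_touchstones(
    reference: Iterable[tuple[SurvivalSurface, DerivativeSet]],
) -> ReferenceTouchstones:
    """Per-cell medians of the reference pool.

    Each of the 11 cells takes the median over the reference compounds that
    have that cell; a cell with no reference values is an error naming it.
    """
    reference = list(reference)
    if len(reference) < 3:
        raise ValidationError(
            f"need at least 3 reference compounds, got {len(reference)}"
        )
    sn_med = {}
    for cell in STANDARD_CELLS:
        values = [s.sn[cell] for s, _ in reference if cell in s.sn]
        if not values:
            raise ValidationError(f"no reference values for survival cell {cell}")
        sn_med[cell] = median(values)
    dc_med = {}
    for t in STANDARD_TEMPERATURES_C:
        values = [d.dc[t] for _, d in reference if t in d.dc]
        if not values:
            raise ValidationError(f"no reference values for dSn/dC at T={t}")
        dc_med[t] = median(values)
    dt_med = {}
    for c in STANDARD_CONCENTRATIONS_M:
        values = [d.dt[c] for _, d in reference if c in d.dt]
        if not values:
            raise ValidationError(f"no reference values for dSn/dT at C={c}")
        dt_med[c] = median(values)
    return ReferenceTouchstones(sn_med, dc_med, dt_med, len(reference))


def phi(sn_value: float, touchstone: float) -> int:
    """1 iff normalized survival is at or above the reference median."""
    if not (np.isfinite(sn_value) and np.isfinite(touchstone)):
        raise ValidationError("phi requires finite values")
    return 1 if sn_value >= touchstone else 0


def chi(derivative_value: float, touchstone: float) -> int:
    """1 iff a derivative is strictly above the reference median
    (ties score 0 -- the tie direction differs from :func:`phi`)."""
    if not (np.isfinite(derivative_value) and np.isfinite(touchstone)):
        raise ValidationError("chi requires finite values")
    return 0 if derivative_value <= touchstone else 1


@dataclass
class CompoundScore:
    """Binary scores and crossing-count aggregates for one compound.

    Bits are ``None`` where the underlying cell was missing; a compound
    with missing bits is non-classifiable on the affected Psi axis but
    still contributes to per-condition Gamma tables where it has data.
    """

    compound_id: str
    phi_bits: dict[tuple[float, float], int | None] = field(default_factory=dict)
    chi_dc: dict[float, int | None] = field(default_factory=dict)
    chi_dt: dict[float, int | None] = field(default_factory=dict)

    @property
    def survival_complete(self) -> bool:
        return all(self.phi_bits.get(cell) is not None for cell in STANDARD_CELLS)

    @property
    def derivative_complete(self) -> bool:
        return all(self.chi_dc.get(t) is not None for t in STANDARD_TEMPERATURES_C) and all(
            self.chi_dt.get(c) is not None for c in STANDARD_CONCENTRATIONS_M
        )

    def phi_sum_T(self, temperature: float) -> int | None:
        """Phi(T): survival crossings summed over concentrations, 0-3."""
        bits = [self.phi_bits.get((c, temperature)) for c in STANDARD_CONCENTRATIONS_M]
        return None if any(b is None for b in bits) else sum(bits)

    def theta_sum_C(self, concentration: float) -> int | None:
        """Theta(C): survival crossings summed over temperatures, 0-2."""
        bits = [self.phi_bits.get((concentration, t)) for t in STANDARD_TEMPERATURES_C]
        return None if any(b is None for b in bits) else sum(bits)

    @property
    def phi_dT(self) -> int | None:
        """Phi(dT): temperature-derivative crossings over concentrations, 0-3."""
        bits = [self.chi_dt.get(c) for c in STANDARD_CONCENTRATIONS_M]
        return None if any(b is None for b in bits) else sum(bits)

    @property
    def theta_dC(self) -> int | None:
        """Theta(dC): concentration-derivative crossings over temperatures, 0-2."""
        bits = [self.chi_dc.get(t) for t in STANDARD_TEMPERATURES_C]
        return None if any(b is None for b in bits) else sum(bits)

    @property
    def psi_survival(self) -> int | None:
        if not self.survival_complete:
            return None
        return sum(self.phi_bits[cell] for cell in STANDARD_CELLS)

    @property
    def psi_derivative(self) -> int | None:
        if not self.derivative_complete:
            return None
        return self.phi_dT + self.theta_dC


def aggregate_scores(
    phi_bits: Mapping[tuple[float, float], int],
    chi_dc: Mapping[float, int] | None = None,
    chi_dt: Mapping[float, int] | None = None,
    compound_id: str = "",
) -> CompoundScore:
    """Assemble a :class:`CompoundScore` from raw bits and re-assert the
    crossing-count identities (Psi = sum of Phi(T) = sum of Theta(C))."""
    score = CompoundScore(
        compound_id,
        phi_bits=dict(phi_bits),
        chi_dc=dict(chi_dc or {}),
        chi_dt=dict(chi_dt or {}),
    )
    if score.survival_complete:
        psi = score.psi_survival
        via_phi = sum(score.phi_sum_T(t) for t in STANDARD_TEMPERATURES_C)
        via_theta = sum(score.theta_sum_C(c) for c in STANDARD_CONCENTRATIONS_M)
        if not psi == via_phi == via_theta:  # pragma: no cover - structural identity
            raise AssertionError("crossing-count identity violated")
    return score


def score_compound(
    surface: SurvivalSurface,
    derivatives: DerivativeSet,
    touchstones: ReferenceTouchstones,
) -> CompoundScore:
    """Binarize one compound's observables against the touchstones."""
    score = CompoundScore(surface.compound_id)
    for cell in STANDARD_CELLS:
        value = surface.sn.get(cell)
        score.phi_bits[cell] = None if value is None else phi(value, touchstones.sn_median[cell])
        if value is None:
            logger.info("%s: missing Sn cell %s excluded from scoring", surface.compound_id, cell)
    for t in STANDARD_TEMPERATURES_C:
        value = derivatives.dc.get(t)
        score.chi_dc[t] = None if value is None else chi(value, touchstones.dc_median[t])
    for c in STANDARD_CONCENTRATIONS_M:
        value = derivatives.dt.get(c)
        score.chi_dt[c] = None if value is None else chi(value, touchstones.dt_median[c])
    return score


def score_cassette(
    surfaces: Mapping[str, SurvivalSurface],
    derivatives: Mapping[str, DerivativeSet],
    touchstones: ReferenceTouchstones,
) -> dict[str, CompoundScore]:
    return {
        cid: score_compound(surfaces[cid], derivatives[cid], touchstones)
        for cid in surfaces
    }


@dataclass(frozen=True)
class DruglikenessCall:
    """Interval membership of a compound on the two Psi axes."""

    compound_id: str
    survival_interval: str | None  # "low" / "high" / None when non-classifiable
    derivative_interval: str | None
    simultaneous_high: bool | None


def classify_druglikeness(
    score: CompoundScore,
    survival_high: tuple[int, int] = SURVIVAL_HIGH_INTERVAL,
    derivative_high: tuple[int, int] = DERIVATIVE_HIGH_INTERVAL,
) -> DruglikenessCall:
    """Call low/high therapeutic-potential intervals from the Psi scores.

    Defaults: survival high = Psi in 4-6, derivative high = Psi in 0-2.
    Non-classifiable axes (missing bits) yield an explicit null call.
    """
    psi_s = score.psi_survival
    psi_d = score.psi_derivative
    s_call = None if psi_s is None else ("high" if survival_high[0] <= psi_s <= survival_high[1] else "low")
    d_call = None if psi_d is None else ("high" if derivative_high[0] <= psi_d <= derivative_high[1] else "low")
    both = None if (s_call is None or d_call is None) else (s_call == "high" and d_call == "high")
    return DruglikenessCall(score.compound_id, s_call, d_call, both)


def gamma_from_values(
    values: Sequence[int | None], support: Iterable[int]
) -> tuple[dict[int, float], int]:
    """Percentage of compounds attaining each value of an observable.

    ``None`` entries (non-scorable compounds) are excluded from the
    denominator; the denominator actually used is returned alongside.
    """
    usable = [v for v in values if v is not None]
    if not usable:
        raise ValidationError("gamma over an empty (or fully non-scorable) group")
    support = list(support)
    for v in usable:
        if v not in support:
            raise ValidationError(f"observable value {v} outside support {support}")
    n = len(usable)
    return {s: 100.0 * usable.count(s) / n for s in support}, n


def interval_probability(
    distribution: Mapping[int, float], interval: tuple[int, int]
) -> float:
    """Gamma of a value interval: the sum of the per-value percentages."""
    lo, hi = interval
    if lo > hi or lo < min(distribution) or hi > max(distribution):
        raise ValidationError(
            f"interval {interval} outside observable range "
            f"[{min(distribution)}, {max(distribution)}]"
        )
    return sum(distribution[v] for v in range(lo, hi + 1))


def adventitious_median_probability(n_conditions: int) -> float:
    """Null probability that one group's median beats another's in every one
    of ``n_conditions`` independent conditions when each comparison is a
    fair coin: (1/2) ** n_conditions."""
    if n_conditions < 1:
        raise ValidationError("n_conditions must be >= 1")
    return 0.5 ** n_conditions


# ---------------------------------------------------------------------------
# group-level Gamma tables

#: observables reported in the per-group Gamma table, with their supports
_PSI_OBSERVABLES = {
    "psi_survival": PSI_SURVIVAL_RANGE,
    "psi_derivative": PSI_DERIVATIVE_RANGE,
}


def _observable_values(scores: Sequence[CompoundScore], name: str, key) -> list[int | None]:
    if name == "phi":
        return [s.phi_bits.get(key) for s in scores]
    if name == "chi_dc":
        return [s.chi_dc.get(key) for s in scores]
    if name == "chi_dt":
        return [s.chi_dt.get(key) for s in scores]
    if name == "Phi":
        return [s.phi_sum_T(key) for s in scores]
    if name == "Theta":
        return [s.theta_sum_C(key) for s in scores]
    if name == "Phi_dT":
        return [s.phi_dT for s in scores]
    if name == "Theta_dC":
        return [s.theta_dC for s in scores]
    if name == "psi_survival":
        return [s.psi_survival for s in scores]
    if name == "psi_derivative":
        return [s.psi_derivative for s in scores]
    raise ValueError(f"unknown observable {name!r}")


def gamma_distribution(
    scores: Sequence[CompoundScore], observable: str, key=None
) -> tuple[dict[int, float], int]:
    """Gamma distribution of one observable over one compound group.

    ``observable`` is one of ``phi`` (key = (C, T) cell), ``chi_dc``
    (key = temperature), ``chi_dt`` (key = concentration), ``Phi``
    (key = temperature), ``Theta`` (key = concentration), ``Phi_dT``,
    ``Theta_dC``, ``psi_survival`` or ``psi_derivative``.
    """
    supports = {
        "phi": range(2),
        "chi_dc": range(2),
        "chi_dt": range(2),
        "Phi": range(4),
        "Theta": range(3),
        "Phi_dT": range(4),
        "Theta_dC": range(3),
        "psi_survival": PSI_SURVIVAL_RANGE,
        "psi_derivative": PSI_DERIVATIVE_RANGE,
    }
    values = _observable_values(list(scores), observable, key)
    return gamma_from_values(values, supports[observable])


def gamma_table(scores_by_group: Mapping[str, Sequence[CompoundScore]]):
    """Tidy Gamma table over all observables for several compound groups.

    Columns: ``group, observable, key, value, percent, n`` where ``n`` is
    the denominator (scorable compounds) behind each percentage.
    """
    import pandas as pd

    rows = []
    specs: list[tuple[str, object]] = [("phi", cell) for cell in STANDARD_CELLS]
    specs += [("chi_dc", t) for t in STANDARD_TEMPERATURES_C]
    specs += [("chi_dt", c) for c in STANDARD_CONCENTRATIONS_M]
    specs += [("Phi", t) for t in STANDARD_TEMPERATURES_C]
    specs += [("Theta", c) for c in STANDARD_CONCENTRATIONS_M]
    specs += [("Phi_dT", None), ("Theta_dC", None)]
    specs += [("psi_survival", None), ("psi_derivative", None)]
    for group, scores in scores_by_group.items():
        for observable, key in specs:
            try:
                dist, n = gamma_distribution(scores, observable, key)
            except ValidationError:
                continue
            for value, percent in dist.items():
                rows.append(
                    {
                        "group": group,
                        "observable": observable,
                        "key": _format_key(key),
                        "value": value,
                        "percent": percent,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows, columns=["group", "observable", "key", "value", "percent", "n"])


def _format_key(key) -> str:
    if key is None:
        return ""
    if isinstance(key, tuple):
        conc, temp = key
        return f"{conc * 1e6:g}uM,{temp:g}C"
    if key in STANDARD_CONCENTRATIONS_M:
        return f"{key * 1e6:g}uM"
    return f"{key:g}C"


def druglikeness_table(
    scores_by_group: Mapping[str, Sequence[CompoundScore]],
    survival_high: tuple[int, int] = SURVIVAL_HIGH_INTERVAL,
    derivative_high: tuple[int, int] = DERIVATIVE_HIGH_INTERVAL,
):
    """Per-group interval probabilities on the two Psi axes.

    Columns: group, n_survival, n_derivative, n_both, and the percentages
    of compounds in the survival-high, derivative-high and simultaneous
    high-high sets.  Percentages are unrounded; round only for display.
    """
    import pandas as pd

    rows = []
    for group, scores in scores_by_group.items():
        calls = [
            classify_druglikeness(s, survival_high, derivative_high) for s in scores
        ]
        s_calls = [c.survival_interval for c in calls if c.survival_interval is not None]
        d_calls = [c.derivative_interval for c in calls if c.derivative_interval is not None]
        both = [c.simultaneous_high for c in calls if c.simultaneous_high is not None]
        rows.append(
            {
                "group": group,
                "n_survival": len(s_calls),
                "n_derivative": len(d_calls),
                "n_both": len(both),
                "pct_survival_high": 100.0 * s_calls.count("high") / len(s_calls) if s_calls else float("nan"),
                "pct_derivative_high": 100.0 * d_calls.count("high") / len(d_calls) if d_calls else float("nan"),
                "pct_simultaneous_high": 100.0 * sum(both) / len(both) if both else float("nan"),
            }
        )
    return pd.DataFrame(rows)
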