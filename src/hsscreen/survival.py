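"""Per-well survival rates, DMSO normalization and survival-surface derivatives.

The assay exposes worms to a compound at 1, 10 and 100 uM under heat shocks
at 38 and 40 C.  For each condition the survival rate S(C, T) is the
fraction of worms alive 24 h after the heat shock, averaged over replicate
wells, and is reported normalized to the matched 1% DMSO control at the
same temperature:

    Sn(C, T) = S(C, T) / S_DMSO(0, T)

Sn may exceed 1 when a compound outperforms the vehicle control.  Two
finite-difference observables summarise how a compound's protection varies
across conditions: a concentration derivative (mean of the two forward
differences over the decade steps 1->10 and 10->100 uM, in 1/M) and a
temperature derivative over the 2 C step 38->40 C (in 1/C).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .cassette import (
    STANDARD_CONCENTRATIONS_M,
    STANDARD_TEMPERATURES_C,
    Cassette,
    SurvivalEntry,
    ValidationError,
    WellObservation,
)

logger = logging.getLogger(__name__)

#: molar steps between consecutive standard concentrations: 10 uM - 1 uM and
#: 100 uM - 10 uM.  Hard-coded for the standard 1/10/100 uM design.
_DC_STEPS_M = (9e-6, 9e-5)
#: temperature step between the two heat shocks, in C
_DT_STEP_C = 2.0

STANDARD_CELLS: tuple[tuple[float, float], ...] = tuple(
    (c, t) for c in STANDARD_CONCENTRATIONS_M for t in STANDARD_TEMPERATURES_C
)


class ControlExtinctError(ValidationError):
    """The DMSO control survival is zero; normalization is undefined."""


@dataclass
class SurvivalSurface:
    """Normalized survival of one compound on the 3 x 2 condition grid.

    ``sn`` maps (concentration [M], temperature [C]) -> Sn.  ``s_control``
    maps temperature -> control survival fraction and is absent when the
    surface was read pre-normalized.
    """

    compound_id: str
    sn: dict[tuple[float, float], float] = field(default_factory=dict)
    s_control: dict[float, float] | None = None

    def __post_init__(self) -> None:
        for cell, value in self.sn.items():
            if value < 0:
                raise ValidationError(
                    f"{self.compound_id}: negative Sn={value} at cell {cell}"
                )

    @property
    def is_complete(self) -> bool:
        return all(cell in self.sn for cell in STANDARD_CELLS)

    @property
    def missing_cells(self) -> tuple[tuple[float, float], ...]:
        return tuple(cell for cell in STANDARD_CELLS if cell not in self.sn)


@dataclass
class DerivativeSet:
    """Finite-difference derivatives of one surface.

    ``dc``: temperature -> dSn/dC approximation (1/M), up to 2 entries.
    ``dt``: concentration [M] -> dSn/dT approximation (1/C), up to 3 entries.
    Missing cells propagate as absent entries, never as imputed values.
    """

    compound_id: str
    dc: dict[float, float] = field(default_factory=dict)
    dt: dict[float, float] = field(default_factory=dict)

    @property
    def is_complete(self) -> bool:
        return set(self.dc) == set(STANDARD_TEMPERATURES_C) and set(self.dt) == set(
            STANDARD_CONCENTRATIONS_M
        )


def survival_rate(alive: int, total: int) -> float:
    """Fraction of worms alive in one well."""
    if total <= 0:
        raise ValidationError(f"undefined well: total={total} must be positive")
    if not 0 <= alive <= total:
        raise ValidationError(f"alive={alive} outside [0, {total}]")
    return alive / total

def mean_condition_survival(
    wells: Iterable[WellObservation], pooled: bool = False
) -> float:
    """Mean survival over the replicate wells of one (compound, C, T).

    Default is the unweighted mean of per-well rates (each well contributes
    equally regardless of how many worms it held).  ``pooled=True`` instead
    pools counts across wells, weighting wells by worm number.
    """
    wells = list(wells)
    if not wells:
        raise ValidationError("mean_condition_survival: empty well collection")
    if pooled:
        return sum(w.alive for w in wells) / sum(w.total for w in wells)
    return sum(survival_rate(w.alive, w.total) for w in wells) / len(wells)


def normalize(s: float, s_control: float) -> float:
    """Normalized survival Sn = S / S_control; may exceed 1."""
    if s < 0:
        raise ValidationError(f"survival must be non-negative, got {s}")
    if s_control <= 0:
        raise ControlExtinctError(
            f"control survival {s_control} is not positive; Sn undefined"
        )
    return s / s_control


def dc_derivative(surface: SurvivalSurface, temperature: float) -> float:
    """Concentration derivative of Sn at one temperature, in 1/M.

    Average of the two forward finite differences over the decade steps,
    with the molar denominators 9e-6 (1 -> 10 uM) and 9e-5 (10 -> 100 uM).
    """
    c1, c10, c100 = STANDARD_CONCENTRATIONS_M
    try:
        sn1 = surface.sn[(c1, temperature)]
        sn10 = surface.sn[(c10, temperature)]
        sn100 = surface.sn[(c100, temperature)]
    except KeyError as exc:
        raise ValidationError(
            f"{surface.compound_id}: missing cell at T={temperature} "
            f"for concentration derivative"
        ) from exc
    return 0.5 * ((sn10 - sn1) / _DC_STEPS_M[0] + (sn100 - sn10) / _DC_STEPS_M[1])


def dt_derivative(surface: SurvivalSurface, concentration: float) -> float:
    """Temperature derivative of Sn at one concentration, in 1/C:
    (Sn(C, 40) - Sn(C, 38)) / 2."""
    t38, t40 = STANDARD_TEMPERATURES_C
    try:
        low = surface.sn[(concentration, t38)]
        high = surface.sn[(concentration, t40)]
    except KeyError as exc:
        raise ValidationError(
            f"{surface.compound_id}: missing cell at C={concentration} "
            f"for temperature derivative"
        ) from exc
    return (high - low) / _DT_STEP_C


def per_molar_to_per_millimolar(value: float) -> float:
    """Convert a concentration derivative from 1/M to 1/mM (display units)."""
    return value / 1000.0


def derivative_set(surface: SurvivalSurface) -> DerivativeSet:
    """All available finite-difference derivatives of a surface.

    Derivatives whose input cells are missing are simply absent.
    """
    out = DerivativeSet(surface.compound_id)
    for t in STANDARD_TEMPERATURES_C:
        try:
            out.dc[t] = dc_derivative(surface, t)
        except ValidationError:
            pass
    for c in STANDARD_CONCENTRATIONS_M:
        try:
            out.dt[c] = dt_derivative(surface, c)
        except ValidationError:
            pass
    return out


def surfaces_from_cassette(
    cassette: Cassette, pooled: bool = False
) -> dict[str, SurvivalSurface]:
    """Build one :class:`SurvivalSurface` per compound from a cassette.

    Raw-count mode: replicate wells are averaged per condition, then each
    treated condition is normalized by the compound's own DMSO control at
    the same temperature.  A compound with no control wells of its own
    falls back to the shared control compound ``DMSO`` if present.  An
    extinct control (S_DMSO = 0) makes that temperature's cells missing
    rather than infinite, and is logged.

    Pre-normalized mode: Sn values are taken as given.
    """
    if cassette.mode == "pre-normalized":
        surfaces: dict[str, SurvivalSurface] = {
            cid: SurvivalSurface(cid) for cid in cassette.compound_ids
        }
        for entry in cassette.normalized:
            surfaces[entry.compound_id].sn[(entry.concentration, entry.temperature)] = entry.sn
        return surfaces

    by_condition: dict[tuple[str, float, float], list[WellObservation]] = defaultdict(list)
    for obs in cassette.observations:
        by_condition[(obs.compound_id, obs.concentration, obs.temperature)].append(obs)

    surfaces = {}
    for cid in cassette.compound_ids:
        if cid == "DMSO":
            continue
        controls: dict[float, float] = {}
        for t in STANDARD_TEMPERATURES_C:
            own = by_condition.get((cid, 0.0, t))
            shared = by_condition.get(("DMSO", 0.0, t))
            wells = own if own else shared
            if wells:
                controls[t] = mean_condition_survival(wells, pooled=pooled)
        surface = SurvivalSurface(cid, s_control=controls)
        for (ocid, conc, temp), wells in by_condition.items():
            if ocid != cid or conc == 0.0:
                continue
            s = mean_condition_survival(wells, pooled=pooled)
            control = controls.get(temp)
            if control is None:
                logger.warning("%s: no control wells at T=%g; cell dropped", cid, temp)
                continue
            try:
                surface.sn[(conc, temp)] = normalize(s, control)
            except ControlExtinctError:
                logger.warning(
                    "%s: control extinct at T=%g; cells at that temperature dropped",
                    cid,
                    temp,
                )
        surfaces[cid] = surface
    return surfaces


def tidy_table(
    surfaces: Mapping[str, SurvivalSurface],
    derivatives: Mapping[str, DerivativeSet],
):
    """Tidy per-cell table with compound-level derivative columns repeated.

    Columns: ``compound_id, conc_uM, temp_C, sn, dc_38, dc_40, dt_1, dt_10,
    dt_100`` (dc in 1/M, dt in 1/C).
    """
    import pandas as pd

    rows = []
    for cid, surface in surfaces.items():
        deriv = derivatives.get(cid, DerivativeSet(cid))
        for (conc, temp), sn in sorted(surface.sn.items()):
            rows.append(
                {
                    "compound_id": cid,
                    "conc_uM": conc * 1e6,
                    "temp_C": temp,
                    "sn": sn,
                    "dc_38": deriv.dc.get(38.0),
                    "dc_40": deriv.dc.get(40.0),
                    "dt_1": deriv.dt.get(1e-6),
                    "dt_10": deriv.dt.get(1e-5),
                    "dt_100": deriv.dt.get(1e-4),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "conc_uM",
            "temp_C",
            "sn",
            "dc_38",
            "dc_40",
            "dt_1",
            "dt_10",
            "dt_100",
        ],
    )
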