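"""Cassette data model and plate/survival-table I/O.

A screening *cassette* is a set of compounds together with either raw
per-well observations (alive / total worm counts at each concentration,
heat-shock temperature and replicate) or pre-normalized survival values
``Sn(C, T)`` as published in supplementary survival tables.  The two
representations are never mixed within one cassette.

Concentrations are stored internally in molar units; the CSV interfaces
accept/emit micromolar (``conc_uM``) because that is how screening plates
are labelled.  The standard assay design uses 1, 10 and 100 uM in 1% DMSO
plus a 1% DMSO control (``conc_uM = 0``), and heat shocks at 38 or 40 C.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)

UM_TO_M = 1e-6


def um_to_m(conc_um: float) -> float:
    """Micromolar to molar.  Division by 1e6 (not multiplication by 1e-6):
    it maps the standard grid {1, 10, 100} exactly onto {1e-6, 1e-5, 1e-4},
    which matters because concentrations are used as mapping keys."""
    return conc_um / 1e6


def m_to_um(conc_m: float) -> float:
    """Molar to micromolar, the exact inverse of :func:`um_to_m` on the
    standard grid."""
    return conc_m * 1e6


#: treated concentrations of the standard assay design, in molar units
STANDARD_CONCENTRATIONS_M: tuple[float, ...] = (1e-6, 1e-5, 1e-4)
#: heat-shock temperatures of the standard assay design, in C
STANDARD_TEMPERATURES_C: tuple[float, ...] = (38.0, 40.0)


class CassetteError(Exception):
    """Base class for cassette construction and I/O failures."""


class SchemaError(CassetteError):
    """A CSV file does not have the documented column layout."""


class ValidationError(CassetteError):
    """A row or record violates a data invariant."""


class CompoundStatus(str, enum.Enum):
    """Development status of a compound.

    Clinical phases are kept separate at parse time; pooling into a single
    ``clinical`` group happens when groups are formed for reporting.
    """

    LAUNCHED = "launched"
    TOOL = "tool"
    CLINICAL_PHASE_1 = "clinical_phase_1"
    CLINICAL_PHASE_2 = "clinical_phase_2"
    CLINICAL_PHASE_3 = "clinical_phase_3"
    PRECLINICAL = "preclinical"
    WITHDRAWN = "withdrawn"
    UNKNOWN = "unknown"

    @property
    def group(self) -> str:
        """Reporting group: clinical phases I-III pool into ``clinical``."""
        if self in (
            CompoundStatus.CLINICAL_PHASE_1,
            CompoundStatus.CLINICAL_PHASE_2,
            CompoundStatus.CLINICAL_PHASE_3,
        ):
            return "clinical"
        return self.value


#: abbreviation key used by published survival tables:
#: L launched; T tool; P preclinical; C-I..C-III clinical phase I-III;
#: W withdrawn; N/A not available.
STATUS_ABBREVIATIONS: dict[str, CompoundStatus] = {
    "L": CompoundStatus.LAUNCHED,
    "T": CompoundStatus.TOOL,
    "P": CompoundStatus.PRECLINICAL,
    "C-I": CompoundStatus.CLINICAL_PHASE_1,
    "C-II": CompoundStatus.CLINICAL_PHASE_2,
    "C-III": CompoundStatus.CLINICAL_PHASE_3,
    "W": CompoundStatus.WITHDRAWN,
    "N/A": CompoundStatus.UNKNOWN,
}


def parse_status(token: str) -> CompoundStatus:
    """Map a status token (abbreviation or full name) to a :class:`CompoundStatus`.

    Unparsable tokens map to ``unknown`` with a logged warning, so a single
    bad annotation does not abort reading a whole table.
    """
    token = token.strip()
    if token.upper() in STATUS_ABBREVIATIONS:
        return STATUS_ABBREVIATIONS[token.upper()]
    try:
        return CompoundStatus(token.lower())
    except ValueError:
        logger.warning("unparsable status token %r mapped to 'unknown'", token)
        return CompoundStatus.UNKNOWN


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    status: CompoundStatus = CompoundStatus.UNKNOWN
    annotation: str = ""


@dataclass(frozen=True)
class WellObservation:
    """Raw counts from one well at one (compound, concentration, temperature).

    ``concentration`` is molar; 0 denotes the 1% DMSO control well.
    """

    compound_id: str
    concentration: float
    temperature: float
    alive: int
    total: int
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError(
                f"well ({self.compound_id}, {self.concentration}, "
                f"{self.temperature}): total must be positive, got {self.total}"
            )
        if not 0 <= self.alive <= self.total:
            raise ValidationError(
                f"well ({self.compound_id}, {self.concentration}, "
                f"{self.temperature}): alive={self.alive} outside [0, {self.total}]"
            )
        if self.concentration != 0.0 and self.concentration not in STANDARD_CONCENTRATIONS_M:
            logger.info(
                "non-standard concentration %g M for %s",
                self.concentration,
                self.compound_id,
            )
        if self.temperature not in STANDARD_TEMPERATURES_C:
            logger.info(
                "non-standard temperature %g C for %s",
                self.temperature,
                self.compound_id,
            )


@dataclass(frozen=True)
class SurvivalEntry:
    """One pre-normalized survival value Sn at one (concentration, temperature)."""

    compound_id: str
    concentration: float
    temperature: float
    sn: float

    def __post_init__(self) -> None:
        if self.sn < 0:
            raise ValidationError(
                f"negative Sn={self.sn} for ({self.compound_id}, "
                f"{self.concentration}, {self.temperature})"
            )


@dataclass(frozen=True)
class Cassette:
    """A set of compounds plus raw-count or pre-normalized observations."""

    compounds: tuple[CompoundRecord, ...]
    observations: tuple[WellObservation, ...] = ()
    normalized: tuple[SurvivalEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.observations and self.normalized:
            raise ValidationError(
                "a cassette is either raw-count mode or pre-normalized mode, never mixed"
            )
        ids = [c.compound_id for c in self.compounds]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate compound ids: {dupes}")
        known = set(ids)
        for obs in self.observations + self.normalized:
            if obs.compound_id not in known:
                raise ValidationError(
                    f"observation references unknown compound {obs.compound_id!r}"
                )

    @property
    def mode(self) -> str:
        return "pre-normalized" if self.normalized else "raw-counts"

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(c.compound_id for c in self.compounds)

    def record(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    def incomplete_compounds(self) -> tuple[str, ...]:
        """Compounds missing one or more of the six standard (C, T) cells.

        Only meaningful in pre-normalized mode, where the six-cell surface
        is the unit of record; raw-count completeness is judged after
        normalization because it also depends on the controls.
        """
        cells = {
            (c, t)
            for c in STANDARD_CONCENTRATIONS_M
            for t in STANDARD_TEMPERATURES_C
        }
        out = []
        for cid in self.compound_ids:
            have = {
                (e.concentration, e.temperature)
                for e in self.normalized
                if e.compound_id == cid
            }
            if self.mode == "pre-normalized" and not cells <= have:
                out.append(cid)
        return tuple(out)


PLATE_COLUMNS = ["compound_id", "status", "conc_uM", "temp_C", "replicate", "alive", "total"]
SURVIVAL_COLUMNS = ["compound_id", "status", "conc_uM", "temp_C", "sn"]


def _open_reader(path):
    handle = open(path, "r", newline="", encoding="utf-8")
    reader = csv.reader(handle)
    return handle, reader


def _check_header(header: list[str], required: list[str], path) -> dict[str, int]:
    index = {name.strip(): i for i, name in enumerate(header)}
    for col in required:
        if col not in index:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return index


def _parse_float(token: str, what: str, row: int) -> float:
    # decimal point only -- parsing must not depend on the process locale
    try:
        return float(token)
    except ValueError as exc:
        raise ValidationError(f"row {row}: cannot parse {what} from {token!r}") from exc


def read_plate_csv(path) -> Cassette:
    """Read a raw-count plate CSV into a raw-count-mode cassette.

    Expected columns: ``compound_id, status, conc_uM, temp_C, replicate,
    alive, total``.  Row numbers (1-based, header = row 1) are named in all
    validation errors.
    """
    handle, reader = _open_reader(path)
    with handle:
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        idx = _check_header(header, PLATE_COLUMNS, path)
        compounds: dict[str, CompoundRecord] = {}
        observations: list[WellObservation] = []
        seen: set[tuple] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            cid = row[idx["compound_id"]].strip()
            status = parse_status(row[idx["status"]])
            conc_um = _parse_float(row[idx["conc_uM"]], "conc_uM", rownum)
            temp = _parse_float(row[idx["temp_C"]], "temp_C", rownum)
            rep = int(_parse_float(row[idx["replicate"]], "replicate", rownum))
            alive = int(_parse_float(row[idx["alive"]], "alive", rownum))
            total = int(_parse_float(row[idx["total"]], "total", rownum))
            key = (cid, conc_um, temp, rep)
            if key in seen:
                raise ValidationError(
                    f"row {rownum}: duplicate well (compound={cid}, conc_uM={conc_um}, "
                    f"temp_C={temp}, replicate={rep})"
                )
            seen.add(key)
            compounds.setdefault(cid, CompoundRecord(cid, status))
            try:
                observations.append(
                    WellObservation(cid, um_to_m(conc_um), temp, alive, total, rep)
                )
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
        return Cassette(tuple(compounds.values()), observations=tuple(observations))


def write_plate_csv(cassette: Cassette, path) -> None:
    """Write a raw-count cassette in the plate CSV schema (RFC-4180, UTF-8)."""
    if cassette.mode != "raw-counts":
        raise ValidationError("write_plate_csv requires a raw-count-mode cassette")
    status = {c.compound_id: c.status for c in cassette.compounds}
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PLATE_COLUMNS)
        for obs in cassette.observations:
            writer.writerow(
                [
                    obs.compound_id,
                    status[obs.compound_id].value,
                    repr(m_to_um(obs.concentration)),
                    repr(obs.temperature),
                    obs.replicate,
                    obs.alive,
                    obs.total,
                ]
            )


def read_survival_table(path) -> Cassette:
    """Read a pre-normalized survival table (columns
    ``compound_id, status, conc_uM, temp_C, sn``) into a cassette.

    Compounds with incomplete 3x2 grids are retained and flagged via
    :meth:`Cassette.incomplete_compounds`.
    """
    handle, reader = _open_reader(path)
    with handle:
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        idx = _check_header(header, SURVIVAL_COLUMNS, path)
        compounds: dict[str, CompoundRecord] = {}
        entries: list[SurvivalEntry] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            cid = row[idx["compound_id"]].strip()
            status = parse_status(row[idx["status"]])
            conc_um = _parse_float(row[idx["conc_uM"]], "conc_uM", rownum)
            temp = _parse_float(row[idx["temp_C"]], "temp_C", rownum)
            sn = _parse_float(row[idx["sn"]], "sn", rownum)
            compounds.setdefault(cid, CompoundRecord(cid, status))
            try:
                entries.append(SurvivalEntry(cid, um_to_m(conc_um), temp, sn))
            except ValidationError as exc:
                raise ValidationError(f"row {rownum}: {exc}") from None
        cassette = Cassette(tuple(compounds.values()), normalized=tuple(entries))
        for cid in cassette.incomplete_compounds():
            logger.warning("compound %s has an incomplete survival surface", cid)
        return cassette


def write_survival_table(cassette: Cassette, path) -> None:
    if cassette.mode != "pre-normalized":
        raise ValidationError("write_survival_table requires a pre-normalized cassette")
    status = {c.compound_id: c.status for c in cassette.compounds}
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(SURVIVAL_COLUMNS)
        for e in cassette.normalized:
            writer.writerow(
                [
                    e.compound_id,
                    status[e.compound_id].value,
                    repr(m_to_um(e.concentration)),
                    repr(e.temperature),
                    repr(e.sn),
                ]
            )


DEFAULT_EXCLUDED_STATUSES = frozenset(
    {CompoundStatus.UNKNOWN, CompoundStatus.WITHDRAWN}
)


def filter_for_analysis(cassette: Cassette, policy: str = "default") -> Cassette:
    """Drop compounds that cannot be placed on the development-status axis.

    The default policy removes ``unknown`` (development not reported) and
    ``withdrawn`` (development discontinued) compounds, mirroring the
    exclusion of unclassifiable entries before druglikeness ranking.
    ``keep-all`` is the identity.  Surviving records are never altered.
    """
    if policy == "keep-all":
        return cassette
    if policy != "default":
        raise ValueError(f"unknown exclusion policy {policy!r}")
    removed = [c for c in cassette.compounds if c.status in DEFAULT_EXCLUDED_STATUSES]
    for c in removed:
        logger.info(
            "excluding compound %s from analysis (status=%s)",
            c.compound_id,
            c.status.value,
        )
    kept = tuple(c for c in cassette.compounds if c.status not in DEFAULT_EXCLUDED_STATUSES)
    if not kept:
        raise ValidationError("no analyzable compounds after exclusion")
    keep_ids = {c.compound_id for c in kept}
    return replace(
        cassette,
        compounds=kept,
        observations=tuple(o for o in cassette.observations if o.compound_id in keep_ids),
        normalized=tuple(e for e in cassette.normalized if e.compound_id in keep_ids),
    )
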