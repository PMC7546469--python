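"""End-to-end orchestration: cassette in, score tables and reports out.

The scoring run composes the pipeline in assay order: per-well survival
rates -> replicate averaging -> DMSO normalization -> finite-difference
derivatives -> reference touchstones -> binary scores and crossing-count
aggregates -> group Gamma tables, druglikeness calls and significance
tests.  The raw-count and pre-normalized input paths converge on the same
surface representation and therefore produce identical scores for the
same underlying data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping

from . import __version__
from .cassette import (
    Cassette,
    SurvivalEntry,
    ValidationError,
    filter_for_analysis,
    read_plate_csv,
    read_survival_table,
)
from .groupstats import pairwise_tests, summarize_group, summary_table
from .scoring import (
    DERIVATIVE_HIGH_INTERVAL,
    SURVIVAL_HIGH_INTERVAL,
    CompoundScore,
    ReferenceTouchstones,
    classify_druglikeness,
    compute_touchstones,
    druglikeness_table,
    gamma_table,
    score_cassette,
    score_compound,
)
from .survival import (
    STANDARD_CELLS,
    STANDARD_CONCENTRATIONS_M,
    STANDARD_TEMPERATURES_C,
    derivative_set,
    surfaces_from_cassette,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one scoring run."""

    input_path: str
    reference_path: str
    mode: str = "raw"  # "raw" or "normalized"
    exclusion_policy: str = "default"
    survival_high: tuple[int, int] = SURVIVAL_HIGH_INTERVAL
    derivative_high: tuple[int, int] = DERIVATIVE_HIGH_INTERVAL
    leave_one_out: bool = False
    out_dir: str = "."
    seed: int | None = None

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        directory does not affect results and is excluded)."""
        fields = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        text = repr(sorted(fields.items()))
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class ScoreBundle:
    """All tables produced by one scoring run."""

    touchstones: ReferenceTouchstones
    scores: "object"  # DataFrame, one row per compound
    gamma: "object"
    group_summary: "object"
    tests: "object"
    druglikeness: "object"
    compound_scores: Mapping[str, CompoundScore] = field(default_factory=dict)


def to_normalized(cassette: Cassette) -> Cassette:
    """Convert a raw-count cassette to an equivalent pre-normalized one."""
    if cassette.mode == "pre-normalized":
        return cassette
    surfaces = surfaces_from_cassette(cassette)
    entries = [
        SurvivalEntry(cid, conc, temp, sn)
        for cid, surface in surfaces.items()
        for (conc, temp), sn in sorted(surface.sn.items())
    ]
    compounds = tuple(c for c in cassette.compounds if c.compound_id in surfaces)
    return Cassette(compounds, normalized=tuple(entries))


def score_pipeline(
    test_cassette: Cassette,
    reference_cassette: Cassette,
    exclusion_policy: str = "default",
    survival_high: tuple[int, int] = SURVIVAL_HIGH_INTERVAL,
    derivative_high: tuple[int, int] = DERIVATIVE_HIGH_INTERVAL,
    leave_one_out: bool = False,
) -> ScoreBundle:
    """Run the full scoring pipeline in memory.

    The reference cassette defines the touchstones.  Reference compounds
    are also scored (against the full-pool touchstones by default, or with
    themselves left out of the medians when ``leave_one_out``) and appear
    in the output tables as group ``reference``.
    """
    import pandas as pd

    test_cassette = filter_for_analysis(test_cassette, exclusion_policy)

    test_surfaces = surfaces_from_cassette(test_cassette)
    test_derivs = {cid: derivative_set(s) for cid, s in test_surfaces.items()}
    ref_surfaces = surfaces_from_cassette(reference_cassette)
    ref_derivs = {cid: derivative_set(s) for cid, s in ref_surfaces.items()}

    ref_pairs = [(ref_surfaces[cid], ref_derivs[cid]) for cid in ref_surfaces]
    touchstones = compute_touchstones(ref_pairs)

    scores = score_cassette(test_surfaces, test_derivs, touchstones)
    for cid in ref_surfaces:
        if leave_one_out:
            pool = [
                (ref_surfaces[o], ref_derivs[o]) for o in ref_surfaces if o != cid
            ]
            own_touchstones = compute_touchstones(pool)
        else:
            own_touchstones = touchstones
        scores[cid] = score_compound(ref_surfaces[cid], ref_derivs[cid], own_touchstones)

    group_of = {
        c.compound_id: c.status.group for c in test_cassette.compounds
    }
    group_of.update({cid: "reference" for cid in ref_surfaces})

    scores_by_group: dict[str, list[CompoundScore]] = {}
    for cid, score in scores.items():
        scores_by_group.setdefault(group_of[cid], []).append(score)

    all_surfaces = {**test_surfaces, **ref_surfaces}
    all_derivs = {**test_derivs, **ref_derivs}
    members_by_group: dict[str, list] = {}
    for cid in all_surfaces:
        members_by_group.setdefault(group_of[cid], []).append(
            (all_surfaces[cid], all_derivs[cid])
        )
    summaries = [
        summarize_group(members, group) for group, members in members_by_group.items()
    ]

    tests_frames = []
    for cell in STANDARD_CELLS:
        values = {
            g: [s.sn[cell] for s, _ in m if cell in s.sn]
            for g, m in members_by_group.items()
        }
        values = {g: v for g, v in values.items() if v}
        label = f"sn@{cell[0] * 1e6:g}uM,{cell[1]:g}C"
        tests_frames.append(pairwise_tests(values, label))
    for t in STANDARD_TEMPERATURES_C:
        values = {
            g: [d.dc[t] for _, d in m if t in d.dc] for g, m in members_by_group.items()
        }
        values = {g: v for g, v in values.items() if v}
        tests_frames.append(pairwise_tests(values, f"dc@{t:g}C"))
    for c in STANDARD_CONCENTRATIONS_M:
        values = {
            g: [d.dt[c] for _, d in m if c in d.dt] for g, m in members_by_group.items()
        }
        values = {g: v for g, v in values.items() if v}
        tests_frames.append(pairwise_tests(values, f"dt@{c * 1e6:g}uM"))
    tests = pd.concat(tests_frames, ignore_index=True)

    score_rows = []
    for cid in sorted(scores, key=lambda c: (group_of[c], c)):
        s = scores[cid]
        call = classify_druglikeness(s, survival_high, derivative_high)
        row = {"compound_id": cid, "group": group_of[cid]}
        for cell in STANDARD_CELLS:
            row[f"phi_{cell[0] * 1e6:g}uM_{cell[1]:g}C"] = s.phi_bits.get(cell)
        for t in STANDARD_TEMPERATURES_C:
            row[f"chi_dc_{t:g}C"] = s.chi_dc.get(t)
        for c in STANDARD_CONCENTRATIONS_M:
            row[f"chi_dt_{c * 1e6:g}uM"] = s.chi_dt.get(c)
        for t in STANDARD_TEMPERATURES_C:
            row[f"Phi_{t:g}C"] = s.phi_sum_T(t)
        for c in STANDARD_CONCENTRATIONS_M:
            row[f"Theta_{c * 1e6:g}uM"] = s.theta_sum_C(c)
        row["Phi_dT"] = s.phi_dT
        row["Theta_dC"] = s.theta_dC
        row["psi_survival"] = s.psi_survival
        row["psi_derivative"] = s.psi_derivative
        row["survival_interval"] = call.survival_interval
        row["derivative_interval"] = call.derivative_interval
        row["simultaneous_high"] = call.simultaneous_high
        score_rows.append(row)

    return ScoreBundle(
        touchstones=touchstones,
        scores=pd.DataFrame(score_rows),
        gamma=gamma_table(scores_by_group),
        group_summary=summary_table(summaries),
        tests=tests,
        druglikeness=druglikeness_table(scores_by_group, survival_high, derivative_high),
        compound_scores=scores,
    )


def run_score(config: RunConfig) -> ScoreBundle:
    """File-level entry point: read inputs per ``config.mode``, score, and
    write the report bundle into ``config.out_dir``."""
    read = read_plate_csv if config.mode == "raw" else read_survival_table
    if not config.reference_path:
        raise ValidationError("reference set required: provide a reference table")
    test = read(config.input_path)
    reference = read(config.reference_path)
    bundle = score_pipeline(
        test,
        reference,
        exclusion_policy=config.exclusion_policy,
        survival_high=config.survival_high,
        derivative_high=config.derivative_high,
        leave_one_out=config.leave_one_out,
    )
    write_bundle(bundle, config.out_dir, config)
    return bundle


def _provenance(config: RunConfig | None) -> list[str]:
    lines = [f"# hsscreen {__version__}"]
    if config is not None:
        lines.append(f"# config {config.digest()} seed={config.seed}")
    return lines


def write_bundle(bundle: ScoreBundle, out_dir, config: RunConfig | None = None) -> None:
    """Write the bundle as CSVs plus a human-readable summary.

    Every file carries a provenance header (package version, config hash
    and seed) in leading ``#`` comment lines.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    header = "\n".join(_provenance(config))
    tables = {
        "scores.csv": bundle.scores,
        "gamma.csv": bundle.gamma,
        "group_summary.csv": bundle.group_summary,
        "tests.csv": bundle.tests,
        "druglikeness.csv": bundle.druglikeness,
    }
    for name, frame in tables.items():
        path = os.path.join(out_dir, name)
        with open(path, "w", newline="", encoding="utf-8") as handle:
            handle.write(header + "\n")
            frame.to_csv(handle, index=False)
    with open(os.path.join(out_dir, "summary.txt"), "w", encoding="utf-8") as handle:
        handle.write(header + "\n")
        handle.write(render_summary(bundle))


def render_summary(bundle: ScoreBundle) -> str:
    """Plain-text run summary: touchstones, group medians, druglikeness."""
    lines = ["Touchstones (reference pool medians)"]
    lines.append(f"  n_reference = {bundle.touchstones.n_reference}")
    for cell in STANDARD_CELLS:
        lines.append(
            f"  Sn({cell[0] * 1e6:g} uM, {cell[1]:g} C) median = "
            f"{bundle.touchstones.sn_median[cell]:.4f}"
        )
    for t in STANDARD_TEMPERATURES_C:
        lines.append(
            f"  dSn/dC({t:g} C) median = {bundle.touchstones.dc_median[t]:.1f} /M"
        )
    for c in STANDARD_CONCENTRATIONS_M:
        lines.append(
            f"  dSn/dT({c * 1e6:g} uM) median = {bundle.touchstones.dt_median[c]:.4f} /C"
        )
    lines.append("")
    lines.append("Druglikeness interval membership (percent of group)")
    for _, row in bundle.druglikeness.iterrows():
        lines.append(
            f"  {row['group']:<12} survival-high {row['pct_survival_high']:5.0f}%  "
            f"derivative-high {row['pct_derivative_high']:5.0f}%  "
            f"simultaneous {row['pct_simultaneous_high']:5.0f}%  "
            f"(n = {row['n_both']})"
        )
    lines.append("")
    return "\n".join(lines)
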