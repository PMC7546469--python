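# Methods

This note documents the models, conventions and numerical choices behind
`hsscreen`, and what the synthetic validation does and does not establish.

## Survival surfaces

A condition's survival is the unweighted mean of its replicate wells' rates:
each well contributes equally regardless of worm count.  This matches the
assay's practice of averaging three technical wells; a pooled-count mode
(weighting wells by worm number) is available via `pooled=True` for users
who prefer the binomially efficient estimator.  The two differ only when
worm counts differ across wells.

Normalization divides by the matched 1% DMSO control at the same
temperature.  Controls are per-compound; a compound without its own control
wells falls back to a shared `DMSO` pseudo-compound if present.  An extinct
control (no survivors) makes that temperature's cells *missing* rather than
raising a run-fatal error or producing infinities — one bad plate should
not kill a cassette run.  Missing cells propagate as missing through
derivatives, scores and group tables; they are never imputed, and every
reported percentage carries its actual denominator.

Concentrations are stored in molar units.  The micromolar→molar conversion
divides by 10⁶ rather than multiplying by 10⁻⁶: the former maps the
standard grid {1, 10, 100} μM exactly onto {1e-6, 1e-5, 1e-4}, which
matters because concentrations serve as mapping keys.

The concentration derivative uses the printed molar denominators 9·10⁻⁶ and
9·10⁻⁵ (the decade steps of the standard design) and averages the two
forward differences; the temperature derivative divides by the 2 °C step.
Both are raw finite differences — no smoothing or dose–response fitting is
applied anywhere, by design.  All arithmetic is double precision; rounding
happens only at report output.

## Touchstone scoring

Medians use the standard convention (odd n → middle order statistic, even
n → mean of the two middle ones).  The binarization tie rules are
deliberately asymmetric and load-bearing for transcribed tables with few
decimals: survival ties score φ = 1 (counted with the upper half),
derivative ties score χ = 0 (counted with the stable half).  With
continuous data, ties are measure-zero.

Reference drugs are scored against touchstones computed from the full pool,
themselves included; with distinct values this places ⌈n/2⌉ of n references
at or above the median in every cell (18/35 ≈ 51.4% for the standard pool),
which is the expected self-scoring baseline, not a bug.  A leave-one-out
mode exists for sensitivity analysis and changes only the reference
compounds' own scores.

Clinical phases I–III are parsed separately but pooled into one `clinical`
group for Γ reporting.  Compounds whose development status is unknown or
withdrawn are excluded before analysis under the default policy
(`keep-all` disables this).  Druglikeness intervals default to
Ψ_survival ∈ 4–6 (high) and Ψ_derivative ∈ 0–2 (high); both are
configurable but the defaults partition each axis exactly.

## Group statistics

Mood's median test builds the 2×2 table of counts above vs. not-above the
pooled grand median — ties with the grand median fall in the "not above"
row — and tests it with a 1-df chi-square, uncorrected by default (Yates'
correction is a flag).  For small samples the chi-square approximation is
anticonservative; the `exact=True` mode replaces the p-value with the
two-sided hypergeometric (Fisher) probability, which provably equals the
exact permutation test of group labels because the pooled grand median is
invariant under relabelling.  The Kolmogorov–Smirnov test and one-way
ANOVA with Tukey's HSD are delegated to scipy; the package adds only tidy
adapters and reporting.

## Synthetic cassettes

The generator emulates the standard screen: per compound, three wells of
20–25 worms (uniform) at each of six treated conditions plus three control
wells per temperature; deaths are binomial draws around a latent expected
survival

    p(C, T) = control(T) · exp(g + b·x + w·x·1[T=40] + ε),   x = log10(C_μM) − 1,

clipped to [0, 1], with group effect g, dose slope b (default −0.1),
dose–temperature interaction w (default −0.1) and compound-level noise
ε ~ N(0, 0.2).  Control survival defaults to 0.5 at 38 °C and 0.2 at
40 °C.  The latent-effect structure is this package's own construction —
the assay defines no generative model — chosen as the minimal form that
reproduces the qualitative behaviour of real screens: survival falling
with dose, temperature derivatives positive at 1 μM and negative at
100 μM, launched compounds beating tool compounds in every cell, and the
reference pool resembling the launched group.  Clipping events are counted
and a degenerate-regime warning fires if most cells clip, since clipping
flattens medians.  RNG streams are keyed per (group, compound index), so
enlarging any group never perturbs the wells of existing compounds at a
fixed seed.

What the simulator does *not* emulate: plate/edge effects, compound
degradation, correlated well failures, DMSO lot toxicity drift, or any
mechanistic (heat-shock-factor pathway) structure.  Green tests on
synthetic cassettes therefore validate the *analysis* — normalization,
scoring, aggregation, ordering recovery — not the biology of any real
screen.

### Ordering-recovery experiment

`recovery_experiment` measures how often the scored high-interval
percentages reproduce a generating group ordering (launched > clinical >
preclinical > tool).  Two recovery notions are reported: `fraction_strict`
(strictly descending Γ(Ψ_survival ∈ 4–6)) and `fraction_weak` (ties
allowed).  Strict recovery is the meaningful notion at moderate noise; in
the exactly noiseless limit group percentages saturate at 0/100 and tie,
so only the weak notion can reach 100% there.

The shipped `recovery_config` uses 60 compounds per group, effects
{+0.6, +0.2, −0.2, −0.6} around a reference effect of 0, noise 0.3, and
controls 0.25/0.15.  These come from a power calculation with three noise
sources: compound-level latent noise, well-level binomial noise (≈0.2 on
the latent scale at these control survivals and ~66 worms per condition),
and the replicate-to-replicate shift of the reference medians themselves
(≈0.06 latent), which moves all groups together and compresses adjacent
gaps.  The resulting per-group true high-interval probabilities sit near
{0.9, 0.7, 0.3, 0.1}, separated by ≳2.6 standard errors at n = 60, giving
strict-recovery power well above 95% over 200 replicates.  Controls are
low enough that the exponential model essentially never clips at these
effects.

## Z-stack viability counting

The assay's image readout exploits that dead worms are motionless: 30
photographs at 0.5 s intervals are z-stacked, and static worms stay sharp
while movers blur.  The published readout was scored by eye; the explicit
algorithm here is this package's design, chosen over optical flow for
determinism and desk-scale speed:

1. segment the first frame (Otsu threshold unless given → connected
   components → minimum area 30 px → minimum contrast 0.1 below
   background, which keeps a wormless noise-only well from segmenting
   into phantom objects);
2. per object, motion score = mean absolute inter-frame intensity change
   within the object mask dilated by 3 px, divided by the object's
   contrast against the background (median intensity outside the mask);
3. score ≤ threshold → dead, else alive; survival = alive/detected.

Every quantity is a difference or ratio of intensities, so the procedure is
invariant to a global intensity offset.  Touching worms are not split (no
watershed); the generator enforces centroid separation and a crowding
warning fires otherwise.

The renderer draws worms as dark ridges of Gaussian cross-section
(σ = 1.6 px) at floating-point coordinates, so sub-pixel motion changes
pixels smoothly; dead worms are pixel-identical across frames before
per-frame Gaussian sensor noise (σ = 0.02 on a 0–1 scale).  Living worms
translate 10 px over the stack and oscillate perpendicular to their
heading (amplitude 2.5 px, five cycles per stack, an integer count so the
net first-to-last displacement equals the drift exactly).  With these
defaults a static object's motion score is ≈0.05 (pure noise over the
mask) and a moving worm's ≥0.08; the default threshold 0.065 sits in that
gap, placed there from pilot renders of the module's own imagery.  At zero
noise, dead scores are exactly 0 and any threshold strictly between 0 and
the weakest live response classifies perfectly.  Magnification and
resolution of the real microscope setup are unspecified; the 256×256,
~40 px-worm geometry is an arbitrary documented choice.

## Problem sizes used in validation

The acceptance suite runs the ordering-recovery experiment at 200
replicates of 275-compound cassettes (~20 s) and the z-stack recovery on
100 wells of 10 worms each (~45 s); property tests use 1,000 random bit
matrices and exhaustive enumeration where the space is small (2⁵–2⁶).
These sizes were chosen so the full suite completes in about two minutes
on one CPU while keeping Monte-Carlo error far from every asserted bound.

## Known limitations

* The pipeline assumes the standard 3 × 2 condition grid; other grids parse
  (with a flag) but derivatives are defined only for the standard one.
* Γ percentages are descriptive; no multiple-testing machinery is applied,
  matching the formalism's probabilistic rather than inferential intent.
* The z-stack counter has no worm-splitting; dense wells undercount.
* Statistical power of Mood's test at screen-typical group sizes (11–35)
  is modest; the exact mode is recommended below n ≈ 20 per group.
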