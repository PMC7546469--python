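# hsscreen

Analysis pipeline for *Caenorhabditis elegans* heat-shock survival drug
screens.

The assay behind this package asks a simple question of every candidate
compound: does it help worms survive an acute heat shock?  Age-synchronized
young-adult worms (~20–25 per well, three replicate wells per condition) are
dosed at 1, 10 and 100 μM in 1% DMSO, heat-shocked at 38 or 40 °C for 3 h,
and scored for survival 24 h later.  Because the heat-shock response recruits
many cytoprotective pathways at once, compounds that improve survival under
it tend to be the kind of robust, well-tolerated molecules that survive drug
development — so the readout doubles as a cheap whole-animal druglikeness
filter sitting between in-vitro screens and preclinical models.

`hsscreen` implements the full downstream analysis for users of this assay
(screening labs and anyone re-analysing published survival tables), plus a
synthetic-data generator and an image-based viability counter so the whole
pipeline runs and can be validated with no laboratory data at all.

## The statistic at the core

For each well, survival is S = (alive worms)/(total worms).  Replicate wells
are averaged per condition and normalized by the matched 1% DMSO control at
the same temperature:

    Sn(C, T) = S(C, T) / S_DMSO(0, T)

giving a six-cell dose–temperature surface per compound (Sn > 1 means the
compound beat the vehicle).  Two finite differences summarise how protection
varies across conditions:

    ∂Sn/∂C ≈ ½ [ (Sn(10,T) − Sn(1,T)) / 9·10⁻⁶ + (Sn(100,T) − Sn(10,T)) / 9·10⁻⁵ ]   (per M)
    ∂Sn/∂T ≈ (Sn(C,40) − Sn(C,38)) / 2                                               (per °C)

A pool of reference drugs (approved medicines) defines eleven *touchstones*:
the medians of the six Sn cells, the two ∂Sn/∂C values and the three ∂Sn/∂T
values.  Every compound is binarized against them:

* φ(C,T) = 1 iff Sn(C,T) ≥ median (ties count up),
* χ = 1 iff a derivative is strictly above its median (ties count down —
  low derivative magnitude means stable protection, so χ = 0 is favourable).

Crossing counts aggregate the bits: Φ(T) = Σ_C φ ∈ 0–3, Θ(C) = Σ_T φ ∈ 0–2,
and the totals Ψ_survival = Σ φ ∈ 0–6 and Ψ_derivative = Φ(ΔT) + Θ(ΔC) ∈ 0–5.
Within a compound group, Γ converts scores to percentages (Γ(0)+Γ(1) = 100
per condition; ΣΓ(Φ) = ΣΓ(Θ) = 100).  A compound is called druglike when it
lands in the high intervals of both axes: Ψ_survival ∈ 4–6 and
Ψ_derivative ∈ 0–2.

## Worked example

Simulate a screen with the standard design (69 test compounds in four
development-status groups plus 35 reference drugs), then score it:

```bash
hsscreen simulate --out sim --seed 7
hsscreen score --input sim/plate.csv --reference sim/reference.csv --out scored --seed 7
```

The score command prints (abridged):

```
Touchstones (reference pool medians)
  n_reference = 35
  Sn(1 uM, 38 C) median = 1.4594
  Sn(1 uM, 40 C) median = 1.7105
  ...
  dSn/dC(38 C) median = -5174.2 /M
  dSn/dT(1 uM) median = 0.1110 /C

Druglikeness interval membership (percent of group)
  launched     survival-high    53%  derivative-high    65%  simultaneous    35%  (n = 17)
  clinical     survival-high    27%  derivative-high    45%  simultaneous     0%  (n = 11)
  preclinical  survival-high    11%  derivative-high    67%  simultaneous     6%  (n = 18)
  tool         survival-high     0%  derivative-high    78%  simultaneous     0%  (n = 23)
  reference    survival-high    46%  derivative-high    54%  simultaneous    20%  (n = 35)
```

Reading this: the touchstone block lists the eleven reference medians that
every compound was binarized against (reference Sn medians above 1 mean the
reference drugs beat the DMSO control).  The druglikeness block gives, per
group, the percentage of compounds in the high interval of each Ψ axis and
in both simultaneously.  The simulator generated launched compounds with the
largest survival effect and tool compounds with the smallest, and the scored
survival-high column recovers exactly that ordering (53 > 27 > 11 > 0%); the
reference group, simulated close to the launched effect, self-scores near
50% by construction of the medians.  `scored/` also receives `scores.csv`
(per-compound bits and aggregates), `gamma.csv` (full Γ tables with
denominators), `group_summary.csv`, `tests.csv` (pairwise Mood and
Kolmogorov–Smirnov tests) and `druglikeness.csv`.

Real data enter the same way: a raw plate CSV with columns
`compound_id,status,conc_uM,temp_C,replicate,alive,total`, or an already
normalized table `compound_id,status,conc_uM,temp_C,sn`
(`--mode normalized`), e.g. transcribed from a publication's supplementary
survival tables.

The image-based readout works on 30-frame well stacks (dead worms stay
sharp, live worms move):

```bash
hsscreen zstack-count well1.tiff well2.tiff --out viability.csv
```

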