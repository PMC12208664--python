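# Methods

## The model

`m6adyn` tracks, for each gene, two transcript species — unmethylated (`A`)
and m6A-methylated (`m6A`) — through a nuclear and a cytoplasmic
compartment. Each species follows the linear system

    dNuc/dt = α − (β + δ)·Nuc
    dCyt/dt = β·Nuc − γ·Cyt

with production α, export β, cytoplasmic decay γ, and an optional nuclear
decay δ (0 by default, so the simpler model without nuclear degradation is
the default). The steady state is `Nuc = α/(β+δ)`, `Cyt = β·Nuc/γ`. All
rates are in arbitrary, mutually consistent inverse-time units; no physical
unit is imposed, and the sampled rates sit near 1.

The two species never interconvert: methylation is modeled as a separate
production channel (α^m6A), not as a conversion of existing unmethylated
transcripts. A deposition/conversion rate would be a different model; it is
deliberately not implemented.

Five read-outs are derived from the four pools: the total gene level; the
methylated fraction of the nuclear, cytoplasmic, and whole-cell pools; and
the Nuc:Cyt abundance ratio. Ratios with an empty denominator return an
explicit `None` marker in the scalar API (NaN in vectorised tables) rather
than raising — an empty cytoplasm has no cytoplasmic methylation level, and
callers should be able to test for that.

Under the baseline parameterisation the methylated species shares the
export rate (β^m6A = β^A) and decays faster in the cytoplasm by a factor
S = 10 (γ^m6A = S·γ^A). Because only the cytoplasmic methylated pool is
selectively removed, three qualitative facts follow analytically and are
enforced as tests:

* nuclear m6A level > whole-cell level > cytoplasmic level for every gene
  with S > 1;
* whole-cell m6A level rises with the Nuc:Cyt ratio across a cohort
  (nuclear genes are sheltered from selective decay);
* scaling both production rates scales all pools and changes no derived
  index (the model is linear in production).

## Variants

Named presets transform a base rate set:

| name | transformation | reading |
|---|---|---|
| `baseline` | β^m6A = β^A, γ^m6A = S·γ^A, δ = 0 | selective cytoplasmic decay |
| `nuclear_decay` | adds δ > 0 (default 1.0) | decay inside the nucleus |
| `export_facilitated` | β^m6A = 10·β^A, γ^m6A = γ^A | m6A acts on export, not stability |
| `export_inhibited` | β^m6A = 0.1·β^A, γ^m6A = γ^A | m6A retains transcripts in the nucleus |
| `ko` | γ^m6A = γ^A | writer knockout: no selective decay |

The export variants are *alternative hypotheses* and therefore also remove
the selective decay; with S = 10 retained they do not produce the
correlation reversal that motivates them (verified numerically: Spearman of
m6A level against Nuc:Cyt is ≈ +0.03 with decay retained versus ≈ −0.57
without, on the standard n = 2000 cohort).

A nuclear decay δ shared by both species rescales all four steady-state
pools of a gene by the same factor β/(β+δ), so every steady-state *index*
is identical to baseline — the robustness of the steady-state correlations
to δ is exact, not approximate. Decay *dynamics* (hence fitted half-lives)
do change with δ.

## Dynamics and numerics

The transient solution is evaluated in closed form per species:
`Nuc(t) = Nss + (Nuc₀−Nss)e^{−bt}` with `b = β+δ`, and
`Cyt(t) = Css + B·e^{−bt} + (Cyt₀−Css−B)e^{−γt}` with
`B = β(Nuc₀−Nss)/(γ−b)`. When `|γ−b| < 1e-9·max(γ,b)` the code switches to
the limit expression with a `t·e^{−γt}` term to avoid catastrophic
cancellation. An adaptive LSODA integration is kept as an independent
route; the two agree to < 1e-6 relative error on random rate sets,
including the exactly degenerate β = γ case, and the analytic steady state
matches the long-time limit of the transient to < 1e-8. The t = 0 column of
every trajectory reproduces the initial state bit-exactly.

`b = 0` is only reachable with β = δ = 0, in which case the nucleus grows
linearly (or stays constant) and the cytoplasm is decoupled; a steady state
is refused when production is positive there. γ = 0 is admissible only for
a species with no influx.

## Cohorts

Population simulations draw α^A, α^m6A, β, γ^A independently from
Gamma(shape = 1, rate = 1) — both production rates from the same
distribution, which the sampling description leaves implicit — and tie
β^m6A, γ^m6A to the variant. n = 2000 (n = 1000 for the perturbation
grids) with a fixed seed is the standard cohort in tests and the acceptance
script; everything is bit-reproducible given (seed, n, distribution
parameters).

Binned summaries use equal-count quantile bins: observations are ranked
with a stable sort (ties broken by input order, which makes bins
deterministic on heavily tied synthetic data) and split so counts differ by
at most one. Two-axis grids apply the same rule per axis; empty cells are
reported missing, not zero. Correlations on multiplicative quantities
(localization ratios, half-life ratios) use natural-log transforms by
default, with the raw scale available.

## Perturbations

A perturbation is an instantaneous rate change at t = 0 applied to a cohort
at its pre-perturbation steady state. Frozen presets: `actd` (α := 0),
`cpt` (α := 0.1α), `ythdf_ko` (γ^m6A := γ^A), `export_block` (β := 0.1β),
`hs_induction` (α := 10α). Production and export targets hit both species
jointly unless a species-specific target is named. The default time grid is
logarithmic on [0, 10/min(positive post-perturbation rates)] so fast and
slow genes both resolve.

Two subtleties found while validating directions, both consequences of the
model rather than implementation choices:

* **Shutoff ordering.** Among genes identical except for γ, the normalized
  methylated-species *abundance* (Nuc^m6A + Cyt^m6A) declines faster for
  larger γ at every timepoint, and `decay_ordering` reports that quantity.
  The whole-cell methylated *fraction* orders the other way in this
  construction: a fast-turnover gene keeps most of its transcripts in the
  nucleus, where the fraction is pinned at its production ratio. At the
  cohort level (rates varying jointly) the fraction does drop faster for
  short-lived genes, which is what the binned shutoff/reduced-production
  checks assert (at a measurement time of 0.5 rate units, inside the
  window where the transient dip is still ordered by half-life).
* **Transients versus new steady states.** Scaling both α rates leaves
  every steady-state index unchanged (linearity), so the rise in m6A level
  and localization after production induction is transient — the nucleus,
  which is methylation-rich, fills first. The export-block rise, by
  contrast, persists in the new steady state. Direction tests therefore
  evaluate trajectories at finite times.

The export-block fold-change grid bins genes by the post-block Nuc:Cyt
ratio and by the KO/WT half-life ratio. The per-gene localization *change*
after a global export block is the same constant for every gene (each
Nuc:Cyt scales by 1/factor), so the ratio itself is the informative axis.

## Half-life estimation

Decay rates come from ordinary least squares of log abundance on time over
a transcription-shutoff course; the slope k (converted to the natural-log
scale whatever base the caller fits in) gives HL = ln 2 / (−k). Only
negative slopes with a two-sided p < 0.05 are reported, matching standard
practice for shutoff courses; an exactly zero-residual fit is assigned
p = 0 so that ideal simulated data passes the filter. The cohort-level
fitter uses a per-gene grid t = {0, 1, 2, 4, 8}·(ln 2/γ^A), mimicking a
shutoff course whose sampling is scaled to gene kinetics; fixed global
grids are supported. Courses are fit on total abundance (both species,
both compartments) without cross-timepoint renormalization, the same
convention used for TPM-based courses. On bi-exponential total-RNA decay
the fitted HL lies between the half-lives of the fast and slow eigenmodes.

## Measurement indices

* **m6A-GI** is operationalized as normalized IP over normalized input per
  paired sample (the exact historical formula lives in an external script;
  the recovery tests against known ground truth define this index's
  fitness). Genes need ≥ 20 input reads per sample, mirroring the
  deamination coverage floor. Optional TMM rescaling is applied within
  each assay before the ratio.
* **m6A-SI** is the input-expression-weighted mean GI of a sample. Under
  pure within-library normalization this mean telescopes to exactly 1 —
  compositional data carry no global scale — so sample-level shifts are
  only detectable against an anchored library size (see the generator
  notes below).
* **GLORI-GI** sums the deamination scores of DRACH-context sites with
  coverage ≥ 20 and score strictly > 0.1, divided by the gene's adenosine
  count.
* **TMM** factors are computed with the standard constants (log-ratio trim
  0.3, abundance trim 0.05, precision-weighted doubly trimmed mean,
  reference = sample whose upper-quartile expression is closest to the
  mean); factors are rescaled to geometric mean 1. The implementation is
  verified against the reference R implementation on a frozen toy matrix
  to 1e-9.
* **Nuc:Cyt LFC** is log2 of TMM-normalized nuclear over cytoplasmic CPM
  with a pseudocount of one read per scaled library, which keeps dropout
  genes finite.
* **PC1 loadings** come from an SVD of the log2, per-gene-scaled GI matrix
  (genes as observations; only complete genes admissible). The sign is
  fixed so the per-sample PC1 profile correlates positively with the
  declared sample order (column position by default), making the
  convention deterministic and stable under ordering-preserving
  resampling. The per-gene loading vector is unit-norm.

## Synthetic data

The generators turn cohort states into the count tables the metrics layer
consumes, with negative-binomial noise (shared dispersion across genes,
`size = 1/dispersion`; dispersion 0 is Poisson). Defaults — depth 10⁶
expected reads, dispersion 0.1, IP background 0.05 — are ordinary bulk
RNA-seq scale. Every generator is a pure function of (cohort, parameters,
seed), and ground-truth columns always accompany the counts.

* Fraction counts: expected count ∝ the gene's pool sum in that fraction.
  Each fraction is sequenced to the nominal depth, so the count ratio
  estimates the true Nuc:Cyt ratio only up to the global nuclear/
  cytoplasmic mass ratio — as in a real fractionation experiment without
  spike-ins.
* IP/input counts: capture modeled per molecule (methylated molecules with
  efficiency 1, unmethylated with the background rate), so the IP library
  size is the capture yield and both tables carry an explicit anchored
  library size — the spike-in analogue. The expected GI is then an affine
  function of the true m6A level, and sample-level comparisons (knockout
  versus baseline SI) have the right direction.
* Deamination sites: per-gene DRACH sites with unconverted counts
  Binomial(coverage, true m6A level), plus non-DRACH decoys at the
  conversion background; coverage Poisson or fixed.
* Shutoff courses: expected counts follow the exact total-abundance
  trajectories, scaled so the t = 0 library has nominal depth, with no
  per-timepoint renormalization (global RNA loss shrinks later libraries,
  as in the real design).

What the generators do **not** emulate: gene-length and GC biases,
per-gene dispersion heterogeneity, fractionation cross-contamination,
antibody sequence preferences, multimapping, or batch structure. Passing
recovery tests therefore demonstrate estimator correctness under clean
counting noise, not robustness to those real-data artifacts.

## Problem sizes

Tests and the acceptance script use n = 2000 cohorts for steady-state
trends, n = 1000 for perturbation grids, n = 500 genes at depth 10⁶ for
recovery experiments, and 100 random rate sets for the analytic/numeric
equivalences — sizes at which every reported statistic is stable to the
third digit across seeds while the whole suite runs in seconds.

## Known limitations

No stochastic (Gillespie) simulation — the model is deterministic ODE. No
splicing, granule sequestration, cell-division dilution, or
methylation-as-conversion. The measurement layer starts at counts:
alignment, peak calling, and single-site scoring are out of scope. Absolute
half-lives from TPM-style courses inherit the no-renormalization bias of
that convention; only ratios and ranks are interpreted.
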