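# Methods

This note records the models madrift implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Drift model and detection probability

MA lines are modelled as populations of `2Ne` haploid genomes evolving by
Wright–Fisher binomial resampling. The population is simulated directly at
its *effective* size: the inference below is defined on the `2Ne` chain, so a
census-size model with a separate offspring-variance mechanism would add a
nuisance parameter without changing the likelihood. Selection is absent by
construction (the experimental design minimizes it); the diffusion fixation
probability `u = (1−e^(−2s))/(1−e^(−4sNe))` is provided only to show how
little weak selection (|s| ≤ 0.01) moves fixation away from the neutral
`1/(2Ne)`. The closed form agrees with an exact absorbing-chain solve to
within 2% for `2Ne ≥ 8` over `|4Ne·s| ≤ 1`; at very small sizes (`2Ne = 4`)
the diffusion limit is ~3% off, which the tests document rather than hide.

For the detection probability `p(2Ne)`, one new single-copy mutation is
introduced per line per generation for `t = 60` generations; a mutation
arising in generation `g` undergoes `t − g` binomial updates, and at
generation `t` a sample of 200 chromosomes is drawn binomially (with
replacement — the only construction consistent with a sample larger than the
population). `p` is the fraction of all `60 × lines` mutations whose
*sampled* frequency exceeds the 0.2 calling cutoff, averaging over all origin
generations including the most recent ones; applying the cutoff to the
sampled rather than latent frequency mirrors read sampling in real data.
Detected sampled frequencies are distributed over 16 half-open bins
`(0.20, 0.25], …, (0.95, 1.00]` to give the expected spectrum `Pᵢ`.

Absorbed trajectories are removed from the simulation loop (absorption is
permanent), which makes the per-mutation cost proportional to the expected
segregation time (~2·ln(2Ne) generations) rather than to `t`; one million
trajectories simulate in well under a second.

## Effective-size and mutation-rate inference

The observed mutant-frequency spectrum (calls pooled across lines, X and
autosomes fitted separately) is scored by the full multinomial log-likelihood
(including the coefficient) against the simulated `Pᵢ` at each integer `2Ne`
in 10…40. The grid stays integer-valued with no interpolation; ties break
toward the smaller value. Each grid point uses a seed derived
deterministically from the master seed and the grid value, so repeated fits
share common random numbers and the profile is smooth. The per-line rate is
`μ = m/(t·2Ne·p·B)`; because the estimator divides by `2Ne·p`, the ~28%
spread of that product across the whole grid bounds the damage from
mis-specifying `2Ne`. The spread statistic is `100·(max−min)/min`; the
alternative `/max` convention would read ~22%, and the choice is recorded
here because it is a genuine ambiguity. At small call counts the pipeline
also reports a pooled rate `Σm / Σ(t·2Ne·p·B)`, which is robust when the
per-line median would be zero.

## Mutation calling

A site is *eligible* when the parental line and at least 10 MA lines each
have 15–250 reads and at most 10 alleles are observed in all lines combined
(boundaries inclusive). At an eligible site, a mutant allele in a line is
called when all six filters pass: (1) zero parental reads supporting it;
(2) two-sided Fisher strand-bias p > 0.001, on the 2×2 table (mutant+,
mutant−, other+, other−) within the mutant line — the standard construction;
(3) at most two alleles with ≥1 read in the mutant line; (4) mutant frequency
strictly above 0.20; (5) no other line with the allele at frequency strictly
above 0.05; (6) at most two other lines with any read (one read counts)
supporting the allele. Multiple candidate lines at one site are evaluated
independently, so the leakage clauses can reject all of them. Relaxing any
single threshold can only add calls (a tested monotonicity property).

Classification partitions allele pairs: equal length with one differing base
is an SBS, with two or more an MBS; a pure length gain/loss (one allele a
subsequence of the other) is an INS/DEL; any length change combined with
substitution is COMPLEX. The normalized Ti/Tv ratio is `2·ti/tv`, since each
site offers one transition and two transversions; mutation bias toward G/C
ancestral bases is `(n_GC/gc) / (n_AT/(1−gc))` given genomic GC content
`gc`. Local context uses a ±20 bp window: GC fraction plus a DUST-style
complexity score `S = Σcᵢ(cᵢ−1)/2 / (w−1)` over overlapping trinucleotides
(single fixed window, no sliding sub-window minimization — the score is used
as a complexity scale, not as a masking filter), reported with `−ln S` and an
infinity sentinel at `S = 0`.

## Variance partitioning and mutational heritability

Trait panels are fitted by REML under the one-way random-effects model
`y = μ + line + e` (bristle-style data add a replicate-within-line term).
The implementation profiles the residual variance and maximizes over the
variance ratio(s) with explicit boundary handling; estimates are truncated
at zero. REML was written in-house rather than wrapped because the
among-line test is a boundary likelihood-ratio test with the
`½χ²₀ + ½χ²₁` null, which requires the null REML log-likelihood on an
identical constant convention; statsmodels MixedLM serves as an independent
cross-check in the tests (agreement to ~0.1%), and the balanced case equals
the closed-form ANOVA estimator to numerical precision. Multiple traits are
FDR-adjusted by Benjamini–Hochberg at 0.05.

The accumulated among-line variance relates to the per-generation mutational
variance via `V_MA = k·Vm`, `k = 2[t − (2Ne−5)(1 − e^(−t/2Ne))]`, with
`2Ne = 21` as default (average of the autosomal and X fits; overridable).
`Ve` depends on the measurement design: pooled expression samples of `n`
individuals have within-line variance `Ve/n + Vr`, so `Ve` is approximated
upward as `n ×` within-line variance (making `h²m = Vm/Ve` conservative);
sleep-style traits use the within-line variance directly; bristle-style
counts add the between-replicate component. Analyses are per sex throughout.

Gene-expression panels are first rank-transformed to quantiles of a normal
with robust moments — mean = median, sd = 1.4824 × MAD, at plotting positions
`rank/(n+1)` with averaged ties. The 1.4824 factor is the normal consistency
constant; a raw-MAD transform is exposed via `scale_factor=1.0` since the
scaling affects only the scale of reported variances, not inference.
Expressed/unexpressed status comes from a two-component Gaussian mixture
(EM, restarts on vanishing components); the cutoff is the smallest value
whose posterior for the high-mean component reaches 2/3. Whether one
component suffices is decided by BIC — a concrete criterion for an otherwise
vague "degenerate" case.

## Sequence-based variance and selection models

The sequence-level analogue of genetic variance is `ΣVar(gᵢ)` over loci,
with dosage `g ∈ [0, 2]` (twice the within-line frequency when segregating)
and the `n−1` sample variance. For MA lines the sum is divided by `k`, and
mutations segregating below the 0.2 cutoff are imputed: the detection
simulation also records the distribution of sampled frequencies in
`(0, 0.2]`, and for `m` detected calls, `m·p_below/p_detect` undetected
segregating mutations are drawn from it (each contributing `(2f)²/n_lines`
to the sum). Lost mutations contribute no variance and are excluded; the
count of sub-cutoff draws is the model-expected number given detection,
since the data do not identify it.

`Vm/Vg` is then compared with `1/(4N)` (neutrality, with `N = π/4μ` from
nucleotide diversity), with the sequence-based ratio `ΣVar(mᵢ)/k ÷ ΣVar(gᵢ)`
(their quotient is exactly the effect-size ratio `E(a²_m)/E(a²_g)`), with the
house-of-cards locus number `n = Vg/(4μVs)` at `Vs` a caller-chosen multiple
of `Ve` (default 20), and with the pleiotropic model's `s = Vm/Vg`.

## What the generator emulates, and what it does not

The synthetic genome is i.i.d. with target GC (default 42.48%, a
Drosophila-like euchromatic composition) and a leading X fraction; real
genomes have isochores, repeats and chromatin structure that i.i.d. sequence
lacks, except that homopolymer runs can be planted to exercise the
slippage–indel association. Mutations arise Poisson(`2Ne·μ·B`) per line per
generation (exactly one per generation in the spectrum-calibration mode),
at infinite-sites positions (collisions re-drawn), with uniform mutant
alleles — so the generator's Ti/Tv is 1.0 by construction and spectrum
summaries on synthetic calls test machinery, not biology. X vs autosome
differ only through separate `2Ne` values; there is no dosage/hemizygosity
model. Read depth is Poisson truncated to the eligibility bounds (no
coverage model is implied by the design; any unimodal count distribution
satisfying the bounds would do), reads split across strands at 1/2,
sequencing errors are uniform base swaps at a per-read rate, and no
alignment or mapping artefacts are simulated. Pileups are rendered only at
mutated plus background sites; a full genome × line table carries no extra
information, and callable bases `B` are estimated by scaling genome length
by the eligible fraction of the background sample. Consequently, passing
tests demonstrate correct recovery of rates and variances *under the stated
noise model*, not robustness to mapping error, contamination, or index
hopping.

Trait panels are balanced Gaussian line + residual draws: an MA panel uses
`v_line = k·Vm`, an inbred standing-variation panel uses `v_line = Vg` or
explicit locus effects (`Vg = effect_var·ΣVar(gᵢ)` as loci grow). Real
expression data add batch, probe and sex-contamination structure that is out
of scope here.

## Problem sizes and numerical choices

Simulation sizes default to 100,000 lines (6 × 10⁶ trajectories) for a
production detection-probability estimate — Monte-Carlo SE ≈ 0.01 percentage
points — and the package's own validation suite uses 25,000–50,000 lines for
detection probabilities and 5,000–6,000 lines per grid point for
grid scans and likelihood fits, sizes at which parameter-recovery
experiments (ML `2Ne` within ±2 in ≥90% of fits at 1,000 binned mutations;
end-to-end `μ̂` median within 15%) hold comfortably. Optimization of REML
ratios is 1-D bounded (or Nelder–Mead for the nested model) on a log scale
with explicit boundary comparison at zero; ratios below 1e−10 are truncated
to exactly zero. The multinomial likelihood returns `−inf` when an observed
bin has zero simulated probability; a fit where every grid point is `−inf`
is flagged impossible rather than silently argmax'd. Spectrum bins are
uniformly half-open `(lo, hi]` (a frequency of exactly 0.25 falls in the
first bin); the strictness of the 0.2 cutoff follows the calling filter
(strictly greater).

## Known limitations

* The detection simulation samples 200 chromosomes, while real calling uses
  read counts at finite depth; at depth 30 this mismatch biases `μ̂` by a few
  percent at most (absorbed within the validated 15% band) but would grow at
  very low coverage.
* The caller's ancestral allele is the parental majority allele; a parental
  line polymorphic at a site (residual heterozygosity) is not modelled.
* `estimate_ne` assumes mutations are unlinked and pooled across lines;
  strong rate variation among lines widens the spectrum relative to the
  model.
* The house-of-cards and pleiotropic summaries are point evaluations of
  equilibrium formulas, not fitted models; they inherit the caller's `Vs`
  multiplier and `N` estimate.
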