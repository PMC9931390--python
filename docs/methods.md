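# Methods

This note records the models behind each `gemscreen` stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Barcode-screen enrichment

Counts for strain *i* in sample *j* are modelled as negative binomial with
mean `s_j · q_i(condition)` and variance `µ + α µ²`, where `s_j` is a
median-of-ratios size factor (ratio of each sample to the per-strain
geometric mean, median over strains expressed in all samples). The log2 fold
change is computed from condition means of normalized counts with a
pseudocount of 0.5, which keeps fold changes finite for zero counts. The
gene-wise dispersion is a moment estimate pooled over the two conditions,
`α̂ = (Σ_c (var_c − µ_c)) / (Σ_c µ_c²)`, clipped to `[1e-8, 10]`. Because
three replicates per condition estimate a variance very poorly, `α̂` is
shrunk in log space toward a parametric trend `α(µ) = a₀ + a₁/µ` fitted
across all strains; the trend weight is 0.7, i.e. the shared trend dominates
and the gene-wise estimate perturbs it. The Wald statistic is
`log2fc / SE(log2fc)` with a delta-method SE built from the NB variance of
each condition mean, referred to the standard normal, with
Benjamini–Hochberg adjustment across tested strains. On simulated null
screens (3000 strains, depth 10⁶, dispersion 0.02) the fraction of strains
flagged at q < 0.05 is ≈ 0.6%, within the nominal level; the normal
reference is slightly optimistic with three replicates, which is the price
of keeping genuinely large effects significant — a heavier-tailed small-
sample reference (e.g. t with 4 df) cleans the null completely but inflates
the q-values of real 30-σ hits several-fold.

Hit calling uses log2fc ≥ log2(16) (or ≤ −log2(16)) and q < 0.05; the
low-count filter drops strains whose *maximum* count over all samples is
below 10, so a strain strongly depleted in one condition but detectable in
the other is retained. The slow-grower cutoff (OD < 0.11 at 24 h on minimal
medium) is applied with a strict inequality. The Fisher overlap test is
one-tailed toward enrichment. The gene-set score is a Welch t of member vs
non-member log2 fold changes, one-sided per direction with per-direction BH;
it is a deliberately simple set statistic, not a reimplementation of any
particular GSEA tool.

## Dose–response and IC50

Relative growth at the endpoint read (default 720 min; plates run 18 h but
strain characterization reads at 12 h) is blank-subtracted OD, replicate-
averaged per dose, divided by the zero-dose mean, clipped at 0. The 4PL
model is fitted by bounded least squares with multi-start initialization
(hill ∈ {0.5, 1, 2, 4} × x₅₀ at each interior dose; best RSS wins, ties
broken by start order, so the fit is deterministic). Two IC50 notions are
kept apart: the curve midpoint `x₅₀`, and the reported **absolute IC50**,
the dose where the fitted curve equals half its fitted zero-dose value,
`ic50 = x₅₀ ((top−bottom)/(top/2−bottom) − 1)^{1/h}`. These coincide when
`bottom = 0`. Curves with less than 20% dynamic range, or whose half-
response lies beyond the tested range, are censored and reported as
"> max dose" rather than extrapolated; censored values propagate through
the daily-resistance heatmap as a top-of-scale category. Generation
accounting for a serial-transfer design is `days · log2(dilution)` with the
completed count as its floor (7 days at 1:200 → 53.507, "~53").

## Breakdown classification

The reporter-strain growth AUC (trapezoidal integral of blank-subtracted OD
over hours, negative values clipped) proxies residual drug in conditioned
buffer. A fast degrader clears drug before the 15-min sampling, so its
buffer lets the reporter grow more than wild-type buffer (one-tailed
greater); a slow degrader leaves drug at 45 min (one-tailed less). The
default test pools the variance (df = 19): with only three knockout
replicates, Welch's t inherits a ~2-df variance estimate whose sampling
noise destroys most of the power (simulated per-strain power 0.4–0.8 at a
3-σ effect versus 0.93–0.99 pooled), while the 18 wild-type replicates pin
the common assay variance down well; pooling assumes homoscedastic AUCs
across strains, which holds for a shared assay protocol. Welch remains
available via ``equal_var=False``.
BH adjustment is applied separately per direction across strains; q < 0.1
assigns the class, and a strain significant in both directions (possible
only pathologically) is demoted to "none" with a warning. Wild-type
replicates collected on different days are pooled.

## Spheroid landscapes

Normalization is per-well growth (`end/t0`) followed by plate scaling
`(v − min)/(secondmax − min)`; the second-largest well, not the maximum,
defines the unit so one outlier well cannot compress the whole plate, and
values above 1 are retained. The poly44 surface (15 monomials `x^m y^n`,
`m+n ≤ 4`) is fitted by ordinary least squares in dilution-index coordinates
rescaled to [0, 1] — serial dilutions are uniform in log concentration, so
index space is effectively a log-dose axis, and the zero-drug column sits at
index 0 (a log axis cannot represent 0 µM). The EC50 front is the 0.5 level
set of the fitted surface, extracted by marching squares on a 500×500
evaluation grid with one Newton correction step along the gradient (front
points satisfy |f − 0.5| < 10⁻³), cross-checked by per-row 1-D root
bracketing; an empty front is a valid result. Front comparisons report
per-row crossing-dose shifts in index (log-dose) units with a sign test.

## Fluctuation analysis

The Lea–Coulson model: mutations occur as a Poisson process (expectation
`m` per culture); a mutation founds a clone whose final size has
`P(j) = 1/(j(j+1))` (tail `P(j ≥ k) = 1/k`); plating a fraction ε thins each
clone to `Binomial(j, ε)` observed colonies. The per-event colony law is

    q_k = Σ_{j ≥ max(k,1)} [1/(j(j+1))] C(j,k) ε^k (1−ε)^{j−k},

computed by truncated summation with a geometric tail bound below 10⁻¹²;
`q₀` has the closed form `1 + (ε/(1−ε)) ln ε` (verified against Monte-Carlo
thinning). The mutant-count pmf follows the compound-Poisson recursion
`p₀ = exp(−m(1−q₀))`, `p_n = (m/n) Σ_k k q_k p_{n−k}`, which at ε = 1
reduces to the classic Ma–Sandri–Sarkar recursion. The MLE of `m` is found
by safeguarded bracketed Brent minimization of the negative log-likelihood
(xatol 10⁻¹², p₀-method starting bracket when zero-count cultures exist);
a Newton iteration would also work, but the bracketed scalar minimizer is
unconditionally stable and matches a dense grid search to < 10⁻³ on every
test dataset. Confidence intervals invert the likelihood-ratio statistic
`2(ℓ(m̂) − ℓ(m)) = χ²₁(0.95)` by bisection, with a closed-form upper bound
when all counts are zero. The per-division rate is `µ = m̂/(Nt − N0)`
(number of divisions); dividing by `Nt` instead is available as an option
and differs negligibly when `N0 ≪ Nt`. Rates are normalized per 1000 bp of
the target gene; locus fold-ratios carry an interval-arithmetic CI from the
profile bounds, with an infinite-ratio sentinel for a zero denominator.
Known limitations: no differential mutant fitness, no death, no phenotypic
lag, no post-plating growth.

## Mutation annotation

Queries are aligned to the reference CDS with a global aligner (match +1,
mismatch −2, gap open −5, gap extend −1) whose *query* end gaps are free, so
up to ~30 bp of vector/primer sequence on either side is soft-clipped while
unaligned reference ends stay penalized — otherwise a near-terminal
insertion can be silently clipped away instead of detected. Classification
order: queries under 50 bp or below 50% identity are "unassigned" unless a
high-identity local alignment covering < 80% of the query marks a
transposon/junction; a query end-clip ≥ 40 bp, or an internal gap ≥ 30 bp,
is a transposon/junction; shorter gaps are indels with a frameshift flag
(`length mod 3 ≠ 0`); substitutions are translated and called nonsense,
missense, or silent ("none"), with nonsense taking precedence when several
substitutions occur. Junctions within ~150 bp of the 3' CDS end are not
distinguishable from truncated reads under this scoring and end up clipped;
promoter mutations are outside the sequenced region by design.

The conservation-bias test ranks conservation scores at missense positions
against the scores of **all** positions (the mutated ones included — an
exclusive-background option exists), one-sided toward higher conservation.
For combined n ≤ 20 the null distribution is enumerated exactly over all
assignments (valid under ties); otherwise the tie-corrected normal
approximation of the rank-sum statistic is used.

## Synthetic generators

All generators take explicit seeds and are deterministic. Defaults encode
the study designs the stages assume: 3680-strain library with 3 replicates
per condition at 10⁶ expected reads per sample; NB dispersion 0.02
(technical-replicate-like spread of a pooled-inoculum screen; baseline
abundances lognormal, σ = 0.5); growth read every 10 min for 18 h; spheroid
grids of 12 doses (1.6-fold dilution plus a zero column) × 8 bacteria
levels; fluctuation cultures with N0 = 730, Nt = 10⁸, ε = 1/40, 10 cultures.
The screen-read generator embeds barcodes between fixed 20-bp flanks
(arbitrary constants — the real amplicon structure is not modelled) and
applies uniform substitution errors; no quality-score structure, adapters,
or indices are simulated. The growth generator scales an entire logistic
curve by the Hill factor `1/(1+(d/IC50)^h)`, so relative growth equals that
factor exactly at every timepoint — real inhibition also distorts curve
shape and lag. The spheroid generator applies a Hill response to the
degradation-discounted effective dose `d·exp(−c·bacteria)`; it does not
model bacterial growth during co-culture or imaging segmentation error. The
fluctuation generator is the exact generative counterpart of the estimator's
likelihood (inverse-CDF clone sizes `j = ⌊1/U⌋` truncated at Nt, binomial
thinning), so recovery tests validate the estimator, not the model's fit to
real colony counts. Mutation-position sampling weights positions by
`bias^{(score−1)/8}` on a 1–9 conservation scale. Passing tests on these
generators therefore demonstrate internal correctness of the estimators
under their assumed models, not robustness to the ways real data deviate
from those models.

Strain IC50 presets pair the most-sensitive (0.7 µM) and most-resistant
(103 µM) strain values with 12-point dose ranges that bracket them; the
Hill slope is set to 2 (not separately reported for these strains, and the
recovered IC50 is slope-independent for noise-free in-model curves).

## Problem sizes in the test suite

The acceptance-style suites run at desk scale: 20 null screens of 3000
strains for FDR calibration, 200 simulations for profile-CI coverage,
100 noisy plates for IC50 recovery, 500 random mutation specs for the
annotation round trip, 100 simulations for conservation-test power.
These sizes give Monte-Carlo error comfortably below the asserted
tolerances while keeping the default `pytest` run to a few minutes.
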