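# Methods

This note records the statistical model behind each component, the
parameters that matter, the numerical conventions, and what the
synthetic generators do and do not emulate.

## Data model

The pipeline's universal input is an `AlleleCountTable`: per locus and
line, the read counts of the minor and major allele, with 1-based
coordinates on named chromosome arms.  "Minor" is defined globally: at
each locus the allele with the smaller read count pooled over *all*
lines (ties keep the input orientation).  The global minor-allele
frequency therefore uses read-count pooling, not a mean of per-line
frequencies — with unequal depths the two differ, and pooling matches
the definition of a frequency "across all lines".

Screening keeps a locus iff every line has coverage in [5, 250]
(inclusive bounds) and the pooled minor frequency is ≥ 0.05.  A line's
own frequency may be below 0.05; only the pooled value counts.  Indels
and SNPs are not distinguished; an optional `variant_type` column rides
along untouched.

## Candidate scan

**DiffStat.**  With success-line frequencies S and failure-line
frequencies F (four each), DiffStat = min(S) − max(F) if min(S) > max(F),
max(F side) symmetric otherwise, else 0.  Inequalities are strict: a
single shared value across regimens yields 0.  The **drift statistic**
is max(range(S), range(F)) — the larger of the two within-regimen
ranges.  Pooling both regimens' ranges (rather than testing each
regimen against its own range) is the conservative reading of
"variation within a selection regimen": a locus must beat the noisiest
regimen.  A locus is a significant-DiffStat locus when
DiffStat > drift statistic (strict).

**Quasibinomial GLM.**  The response is the (minor, major) count pair —
counts, not depth-weighted frequencies — with a logit link and the
regimen factor as sole covariate.  With one two-level factor the IRLS
fit has a closed form: fitted group proportions are the pooled count
ratios.  Dispersion is estimated from the full model's Pearson X² over
its residual df (k − 2 lines), and the analysis-of-deviance F statistic
(D₀ − D₁)/φ̂ is referred to F(1, k − 2) — df (1, 6) for the 4+4 scan,
(1, 5) for a 4-vs-3 regimen-versus-control contrast.  The closed form is
verified against an independent IRLS fit to 1e−8 in the tests.  Edge
cases: no deviance difference → F = 0, p = 1; positive deviance
difference with φ̂ < 1e−12 → F = +∞, p = 0 with a degenerate-dispersion
flag (each line sits exactly on its group proportion, so there is no
residual variation to scale by).

**q-values.**  Storey's estimator: π₀(λ) = #{p > λ}/(m(1 − λ)) on
λ = 0.05…0.95, smoothed by a natural cubic smoothing spline (penalty by
generalized cross-validation) and evaluated at λ = 0.95, clipped to
(0, 1]; then q₍ᵢ₎ = min over j ≥ i of π₀·m·p₍ⱼ₎/j.  With π₀ fixed at 1
this is exactly Benjamini–Hochberg, which the tests assert.

**SDVs** are loci passing both criteria.  The scan also reports the
largest raw p-value among q-significant loci — the data-dependent
significance threshold of the GLM route.

**Control contrasts.**  Success-vs-control and failure-vs-control GLMs
are q-adjusted separately; a locus counts as oppositely diverged when
both contrasts are significant and the regimen means deviate from the
control mean with opposite signs (sign of the mean difference; the
simplest reading of "opposite directions").

## Windows and regimen comparisons

Windows are 50 kb long, stepped by 10 kb, built per arm over the
*observed* locus extent (anchored at the first observed locus, the last
window starting at the largest anchor that fits; arms shorter than one
window get a single window covering their extent).  Anchoring at the
data rather than coordinate zero reflects that telomeric/centromeric
deserts contribute no loci.  Window coordinates are 0-based half-open
internally and in BED exports.

Per window and line the He = 2p(1 − p) of contained loci is averaged
arithmetically; empty windows are missing and excluded from medians.
Enrichment per window is the upper-tail hypergeometric probability of
drawing s SDVs in n variants given the window's arm totals (N variants,
K SDVs), q-adjusted across all windows genome-wide; a window is enriched
at q ≤ 0.05.  The arm-distribution null resamples sets of
|significant-windows| windows without replacement (the per-arm counts of
such a set are multivariate hypergeometric, which is sampled directly)
and flags arms whose observed count falls outside the 2.5–97.5
percentile band.

The regimen t test compares the per-line median window He with a
pooled-variance two-sample t (df = 6 for 4+4 lines), signed as
failure − success so positive t means more heterozygous failure lines.
P_S<F is the fraction of DiffStat loci where the mean of the four
success-line He values is strictly below the failure-line mean (ties
count as not-less; mean-of-line-He was chosen over He-of-mean-frequency
because it weights lines, not reads).  The starting-frequency null
resamples, with replacement, sets of |SDV| control-line mean frequencies
from all loci and compares the observed SDV median to the 2.5th
percentile of the resampled medians.

**LD-decay profile.**  GLM p-values are binned by distance to the
nearest SDV in 50 bp non-overlapping bins up to 20 kb.  A locus that is
itself an SDV measures distance to the nearest *other* SDV, so fully
significant linkage blocks still populate the short-distance bins.
Smoothing is a 5-bin moving average weighted by bin occupancy (sparse
distant bins would otherwise inject spurious maxima).  The independence
distance is where the smoothed curve first reaches its plateau —
operationally, the first bin within 5% of the plateau level, with the
plateau estimated as the median of the far half of the profile rather
than the raw maximum, again for noise robustness.  Profiles whose
smoothed range is below 0.05 carry a no-decay flag (a flat profile has
no meaningful peak).

## F_ST

The default estimator is Weir & Cockerham (1984) for two populations in
its haploid (allele-count) form, treating each read as one sampled
allele so read depths act as sample sizes.  Per-locus variance
components are combined across loci as a ratio of averages; loci
monomorphic across both lines contribute zero to both sums, and a
fully monomorphic comparison returns NaN with a warning.  A `hudson`
switch (Bhatia et al. 2013) is provided because absolute F_ST levels are
estimator-dependent; the between-regimen difference DF_ST is robust to
the choice, which is what the drift study relies on.  Slightly negative
estimates under no differentiation are expected and not clipped.

## Neutral drift study

Each replicate simulates independent biallelic loci: a starting
frequency drawn with replacement from the start pool, 14 generations of
binomial(2N) resampling in four success lines (N = N_success) and four
failure lines (N = N_failure), then pool-seq observation (depth drawn
with replacement from the coverage pool, reads binomial) and the same
pooled-MAF ≥ 0.05 screen as the real data, re-simulating until the
target locus count is reached (error after 100 × n_loci candidate
draws).  The four relaxed-selection generations of the original design
are excluded, as their census sizes were large enough to make drift
negligible.  Loci are independent by construction — the study design
spaces real loci by the LD-decay distance for exactly this reason.

Replicate statistics: DF_ST (mean within-regimen pairwise F_ST, success
minus failure), P_S<F over the replicate's DiffStat loci (NaN when there
are none; excluded from means), DHe (mean per-line median He, failure
minus success), and the DiffStat/significant-DiffStat counts.  These are
computed by the same functions used on real tables, and a test asserts
that a replicate's internal statistics equal a re-analysis of its
emitted count table.

Defaults encode the study conditions: lines of N = 50 (25 males + 25
females), t = 14 generations, coverage pool a rounded normal(30, 7.5)
truncated to [5, 250] (~96% of depths in 15–45, mean 30), and a start
pool of Beta(0.4, 9.1) truncated to [0.05, 0.5].  The Beta shape was
solved by quadrature so the *truncated* spectrum has mean 0.120,
matching the control lines' mean rare-allele frequency of ~0.12 as
measured on loci passing the 0.05 screen; both shape parameters and the
bounds are config-exposed.

Randomness: one root seed; per-cell and per-replicate `SeedSequence`
children are spawned deterministically, so any replicate can be
reproduced in isolation.

## Synthetic selection experiment

The generator adds bidirectional selection to the drift machinery:
per generation, causal loci are updated by the genic recursion
p′ = p(1 + s)/(1 + ps) with s favouring the minor allele in failure
lines and −s in success lines, controls neutral; then binomial drift;
finally pool-seq observation.  Selection acts on allele frequency
directly rather than through a phenotype model — the original
experiment selected on phenotype, but frequency-level ground truth is
all the pipeline needs, and any phenotype model would add unidentified
parameters.  Loci are laid out across five synthetic arms (2L, 2R, 3L,
3R, X) at a configurable spacing so the window machinery is exercised.

Options: `causal_rare_quantile` plants causal loci among the lower tail
of starting frequencies (for testing the rare-allele signature);
`linkage_block_bp` makes neighbouring loci share one latent trajectory
with independent read noise (an all-or-nothing stand-in for LD, used to
exercise the decay profile — real LD decays continuously).

A saturation effect worth knowing: strong selection (s ≳ 0.6) carries a
rare favoured allele *past* frequency 0.5 within 14 generations, so He
falls in both regimens at causal loci and the P_S<F signal inverts even
though divergence (and hence SDV detection) is maximal.  Moderate
coefficients (s ≈ 0.3–0.5) reproduce the qualitative pattern of the
biology: He up in failure lines, down to near zero in success lines.

What passing tests on this generator do **not** show about real data:
no continuous LD, no variation in recombination or mutation along arms,
no phenotype-mediated selection, no dominance, and read sampling is
ideal binomial (no mapping or calling error).  The generator's role is
ground truth for machinery, not a population-genetic forecast.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the
study: drift cells of 500 loci × 200 replicates, 50,000 trajectories
for the analytic He-decay check, and a 5,000-locus experiment for
parameter recovery — sizes chosen so the whole suite completes in well
under a minute per component while keeping Monte-Carlo standard errors
far smaller than the effects being checked.  `run_drift_study` scales
to the full 12,424-locus, 1,000-replicate sweep unchanged.

## Known limitations

- The quasibinomial F test on 8 lines is approximate; its null rejection
  rate is calibrated against the IRLS oracle, not guaranteed nominal.
- Pool-seq depths understate evolutionary sample sizes when depth
  exceeds the pool's allele count (2 × 70 here); treating reads as
  alleles therefore biases absolute F_ST slightly, another reason only
  DF_ST comparisons are interpreted.
- The arm-resampling and starting-frequency nulls condition on the
  observed SDV count; they do not propagate uncertainty in the SDV calls
  themselves.
- `pi0` estimation needs a reasonably dense p-value grid; with very few
  loci the smoother falls back toward π₀ = 1 (conservative).
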