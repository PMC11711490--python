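# Methods

`ctdetect` detects circulating tumour DNA (ctDNA) in plasma cell-free DNA
(cfDNA) from deep whole-genome TAPS sequencing by comparing three
independent genomic signals of a test sample against a small cohort of
non-cancer reference samples, and integrating the evidence into a single
per-sample cancer call. This note records the models, the tunable
parameters, the numerical choices, and the limits of what the synthetic
experiments demonstrate.

## Reference-cohort scoring (all modalities)

Every modality reduces a sample to per-feature values `y_k` (features are
chromosome arms for coverage and mutation burden, marker regions for
methylation). With reference mean `m_k` and standard deviation `s_k`
(ddof = 1) over `N` reference samples,

    z_k = (y_k - m_k) / s_k
    t_k = z_k / sqrt(1 + 1/N)      ~ t with N-1 degrees of freedom

under a normal model with the sampling variability of `m_k` propagated
(`s_k`'s estimation error is what replaces the normal law by the t law).
With the default 9-sample reference cohort, p-values therefore come from a
t distribution with 8 degrees of freedom. Coverage is tested two-sided
(gains and losses); mutation burden and methylation are tested upper-tailed
— only increases are biologically expected for those signals — and the
sidedness is configurable. Per sample, p-values are Benjamini–Hochberg
corrected across that modality's features; features with `q < alpha`
(default 0.05) are called aberrant.

A modality's integrated score Stouffer-combines the *uncorrected* p-values
of the aberrant features: `z_m = sum(Phi^-1(1 - p_k)) / sqrt(K)`,
`p_m = 1 - Phi(z_m)`. A sample with no aberrant feature is neutral by
convention (`z_m = 0`, `p_m = 0.5`), matching the all-zero integrated
scores of reference controls and making an absent modality harmless under
further combination. Features with `s_k = 0` are excluded with a warning
rather than floored: a degenerate reference conveys no scale. Probit
transforms clip p to `[1e-300, 1 - 1e-16]` to stay finite.

## Coverage / copy-number pipeline

1 kb non-overlapping bins are counted with any-overlap semantics (a read
spanning a bin boundary increments both bins) over properly paired,
non-duplicate, primary alignments with MAPQ > 30. Bins hit by blacklist
regions, with mappability < 0.5, or with GC outside `[0.3, 0.7]` (the
bounds are configurable; extreme GC indicates artefact-prone bins) are
masked and carry no signal downstream. The signal is
`y = log2(count / genome-wide median)`; unmasked bins with zero counts have
no finite log-ratio and are masked at this step.

GC and mappability bias is removed by subtracting an additive smooth fit of
`y` on the two covariates (penalised cubic B-splines via statsmodels'
generalized additive model; the contract is residual decorrelation from
both covariates, and a binned-median correction is the fallback if the fit
fails), followed by re-centring on the mean. Systematic structure shared
with a panel of non-cancer samples is removed by projecting onto the
orthogonal complement of the panel's left-singular-vector span
(`y <- y - U U^T y`; the panel is pre-processed identically). The track is
then Savitzky–Golay smoothed (order 3, window 1001 bins — the nominal
1000-bin window must be odd) per chromosome over consecutive unmasked bins
(masked bins are spliced out, not interpolated; a short chromosome shrinks
the window to the largest odd length that fits), and finally re-centred on
the median. The arm-level feature is the arithmetic mean of the smoothed
signal over the arm's unmasked bins; arms with fewer than 100 unmasked
bins are dropped.

## Somatic mutation burden

TAPS converts methylated cytosines so that true methylation shows C>T
support on one strand orientation only; matching ratios on both
orientations indicate a variant, and support on both at clearly different
ratios indicates a co-located variant and methylation. Sites are
disambiguated with an absolute ratio tolerance of 0.1 and a minimum depth
of 10 per orientation (both configurable; no canonical values exist).

Candidate somatic calls (normalised: decomposed, trimmed — unnormalised
indel representations are refused) are cleaned in order: germline-variant
subtraction (exact `(chrom, pos, ref, alt)` key), germline and cfDNA
methylation-position subtraction, hard thresholds (SNVs excluded when
DP > 200 or DP < 50, MQ < 60, MQBZ < −9, RPBZ outside [−5, 5], MQ0F > 0,
BQBZ < −4, VAF outside [0.03, 0.3]; indels by the DP and VAF rules only —
all strict inequalities, so boundary values survive), removal of records
present in any panel-of-normals sample (exact key; a same-position,
different-allele record is kept), and restriction to non-synonymous
consequences (missense, nonsense, splice-site, frameshift, in-frame indel,
start/stop-altering). Counts removed per step are recorded as provenance.
The arm feature is `log10(count + 1)`; the pseudocount makes an empty arm
score exactly 0 rather than −inf.

## Fragment-level methylation

Markers are built from differentially methylated CpGs: each
hypermethylated CpG contributes `[pos - 100, pos + 100)`, overlapping
intervals merge, regions with fewer than 3 CpGs are discarded, and
hypomethylated regions are discarded outright (baseline methylation at
hypermethylated markers is near zero in non-cancer plasma, so any signal
there is informative). A fragment covering ≥ 3 callable CpGs (base quality
≥ 30) in a marker is tumour-originating when ≥ 80% of its callable CpGs
carry the TAPS modification. The comparison is `>= 0.8`, not `> 0.8`: the
enumerated allowance (a 5-CpG fragment may have one unconverted CpG, i.e.
4/5 = 80% passes) forces the inclusive bound, and it reproduces
`max unconverted = floor(n/5)` for every n. Markers with any
tumour-classified fragment in any non-cancer control sample are excluded.
The per-marker feature is the empirical logit
`log((n_tumour + 0.5) / (n_fragments - n_tumour + 0.5))` — finite at the
0 and 1 fractions that curation makes common; markers with no fragments in
a sample are dropped from its scoring with a warning.

## Multimodal integration

Modality scores combine by weighted Stouffer on the z scale,
`z = sum(w_m z_m) / sqrt(sum(w_m^2))`, `p = 1 - Phi(z)`, with equal weights
by default and a cancer call at `p < 0.05`. Fisher's method
(`S = -2 sum(log p_m)`, chi-square with 2M df) is a drop-in alternative.
Missing modalities are simply absent; zero-weight modalities drop out.
Screening arithmetic converts (sensitivity, specificity, prevalence) into
NPV/PPV by Bayes' rule, and longitudinal tracking reports the percent
reduction of the combined score between timepoints.

The leave-one-out harness evaluates integration rules (no training) or
pluggable classifier cores (logistic regression, random forest, SVM,
L1-penalised multinomial regression — standard algorithms at fixed default
hyperparameters; only the multinomial penalty is tuned, in an inner
leave-one-out loop on training data). Class imbalance is handled by
per-case weights `max(n_1, n_2, ...) / n_g`. Classes with a single member
are excluded from multi-class runs (a model that never saw a class cannot
predict it), and the report stays in multi-class mode (balanced accuracy +
confusion matrix) even if exclusions leave two classes.

## ctDNA fraction

The smoothed coverage is subsampled every 1000 bins per chromosome and
segmented into constant-mean pieces by recursive binary segmentation: a
split is accepted when it reduces the within-segment sum of squares by
more than a penalty `3 * sigma^2 * log(n)`, with `sigma^2` estimated
robustly from first differences (median absolute difference / 0.6745,
halved in variance) so that breakpoints do not inflate it; a noiseless step
is always recovered. Adjacent segments whose means differ by less than 3
pooled standard deviations are then merged (pooled, because the rule's SD
is otherwise unattributed). Per-segment statistics (`N_k`, `m_k`, `s_k^2`,
floored at 1e−6) are computed on the untransformed coverage
`x = 2^(y + 1)`, whose expectation under a mixture of diploid normal cells
and tumour cells of average segment ploidy `c_k` is
`2(1 - rho) + rho c_k`.

With `x_ki ~ Normal(2(1-rho) + rho c_k, s_k^2)` and uniform priors
`rho ~ U(0, 1)`, `c_k ~ U(0, c_max = 4)`, both conditionals are conjugate
normals truncated to the prior supports, sampled by inverse-CDF. The chain
runs 10 000 iterations with a fixed 5 000 burn-in (configurable; no
convergence gate is enforced, matching the fixed-length design), is
initialised at `rho ~ U(0,1)`, `c_k = 2`, and is reproducible under a
seed. A sample whose segment means all sit within 0.05 of 2 is flagged
unidentifiable — the likelihood is then flat in `rho`.

The (rho, c) parametrisation is ridge-unidentified: `m_k - 2 = rho
(c_k - 2)` is invariant under `rho -> rho/a`, `(c_k - 2) -> a (c_k - 2)`,
so with unknown ploidies the data only bound the fraction from below by
`rho_min = max_k |m_k - 2| / max(2, c_max - 2)`, and the posterior spreads
along the ridge above that bound. Posterior summaries are reported as
specified, with the bound exposed (`identifiability_bound`); conditional on
known ploidies the fraction is sharply identified.

## In silico dilution simulation

Validation cohorts are simulated on the summary-feature level (arm
coverage, arm log-burden, marker empirical logit), not on reads. Controls
draw each feature from `Normal(m_k, s_k^2)`; `s_k` is treated as a
standard deviation throughout. Cases mix a tumour template of known
fraction `rho` with a fresh control draw: `y_k = w x_k^t + (1 - w) x_k^h`,
`w = r / rho`, so a target fraction equal to the template's reproduces the
template exactly and `r -> 0` degenerates to the control law. Each sample
(fresh `x_k^h` per case) is scored by the same reference-cohort machinery
(vectorised, verified against the scalar path), and discrimination is
summarised by rank AUC (ties at half credit) per fraction. The default
sweep is ten fractions from 0.1% to 2% with 1000 cases and 1000 controls
each — 20 000 samples.

The bundled synthetic templates (`make_synthetic_templates`) emulate a
colorectal-like profile: 39 arms and 377 markers; control arm aggregates
near zero with per-arm SDs of a few thousandths of a log2 unit; ~0.7
log-burden per arm; near-zero marker methylation around elogit ≈ −4.1; a
9%-fraction template with 12 arm events of single-copy size, 15
elevated-burden arms and 150 hypermethylated markers. The mixture operates
on the elogit scale for methylation (one consistent feature scale across
modalities); mixing raw fractions before the logit would make the diluted
methylation signal stronger, so the simulated methylation limit of
detection is conservative.

## Synthetic on-disk study (`generate_fixture`)

The fixture generator emits a complete miniature study in the formats the
pipeline reads: a 2 × 12 Mb genome binned at 1 kb with smooth GC and
mappability tracks, a blacklist, p/q arm definitions; Poisson coverage
counts at depth 100 per bin around an expectation combining a smooth GC
bias (0.3 log2 peak-to-trough), rank-3 shared low-rank noise (what the SVD
panel removes), and arm-level copy-number factors at 5% tumour fraction
(default: chr1p gain to c = 4, chr2q loss to c = 0) for the test sample;
9 reference and 21 panel samples; candidate/germline/panel VCFs with
background somatic calls (~5 per arm), 60 calls on one elevated arm, 50
artefacts each violating one filter rule, and panel-shared records; and
fragment tables over ~50 markers with ~30 fragments per marker, a 2%
background modification rate, a planted 20% tumour-fragment fraction on 10
markers, and 2 markers deliberately flagged in a control to exercise
curation.

What the fixture does *not* emulate: read-level error profiles and TAPS
conversion chemistry, replication-timing covariates, fragment-size biology,
inter-individual germline variation, and the long-range correlation
structure of real mappability. Passing the end-to-end tests therefore
demonstrates that the statistical machinery recovers planted signals under
Poisson noise with shared structure and realistic masking — not clinical
performance on real plasma.

## Null calibration, problem sizes, and limitations

- Under the global null the multimodal call rate is somewhat above the
  nominal 5% on the synthetic study (roughly 7–15% across fixture
  realisations). The dominant cause is the methylation feature: the
  empirical logit of a zero-signal marker is a heavy-tailed function of
  the Poisson fragment count, so the t(8) tail is anti-conservative; the
  coverage arm residuals are also slightly heavier-tailed than normal
  after debiasing. This is a property of the scoring model at a 9-sample
  reference, not of the implementation; with larger reference cohorts the
  effect shrinks.
- The sensitivity of the simulated dilution series depends strongly on the
  template effect-size-to-reference-SD ratios; the bundled templates are
  deliberately moderate, so discrimination emerges between 1% and 2%
  simulated fraction rather than at the sub-1% fractions achievable with
  stronger templates.
- Test and acceptance runs use scaled problem sizes chosen for desk-scale
  reproducibility: a 24 Mb two-chromosome genome (4 arms), 10 zero-
  aberration replicates for the specificity property, 200 or 1000
  samples per simulated group, 1e5 draws for conditional-law checks, and
  20-segment synthetics for fraction recovery.
- Arm definitions, blacklists and GC/mappability tracks are inputs; the
  package ships none for real genomes. Segmentation is a contract
  (noiseless-step recovery plus the 3-SD merge) implemented by binary
  segmentation rather than circular binary segmentation.
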