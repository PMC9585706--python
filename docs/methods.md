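# Methods

This note documents the models and procedures implemented in `brcastrat`,
their assumptions, the tunable parameters and their defaults, the design
choices made where the underlying procedure was genuinely open, and the
limits of what the synthetic-cohort tests demonstrate.

## BRCA-state assignment

Tumors partition into `BRCAmut`, `BRCA1meth` and `nonBRCA`. A pathogenic
*BRCA1* or *BRCA2* mutation takes precedence over a methylation call: the
two alteration modes are treated as exclusive categories and no
co-occurrence semantics are defined. *BRCA2* promoter methylation is never
assessed — epigenetic *BRCA2* silencing is an extremely rare event and is
deliberately out of scope.

Quantitative methylation (MS-ddPCR percent of methylated templates) is
corrected for neoplastic cellularity by simple tumor-fraction rescaling,
`corrected = min(100, raw / cellularity)`. The exact published correction
procedure is not specified beyond the fact that a cellularity correction was
applied; rescaling by the tumor fraction is the most parsimonious choice and
is monotone, so the high/low dichotomy is unaffected by its precise form for
samples away from the threshold. Thresholds: 70% (ovarian convention, with
cellularity correction) or 60% (TNBC convention, absorbing ~10% typical
normal-tissue contamination in place of a per-sample correction; applied to
raw values). Threshold comparisons are inclusive (`>=`); the dichotomy is
stated in the literature without boundary semantics, and an inclusive
boundary keeps "exactly at threshold" cases in the high (fully methylated)
class. Methylation-array data use the mean beta-value over the four minimal
promoter probes (cg19531713, cg19088651, cg08993267, cg04658354), calling
methylation strictly above 0.4; missing probes are simply dropped from the
mean, with at least one required.

## HRD scoring

**Sequence-based.** The SBS96 spectrum is the 96-vector of single-base
substitutions in their ±1 bp trinucleotide context, pyrimidine-centric
(purine-reference variants are reverse-complemented), channels ordered
substitution-major (`A[C>A]A … T[T>G]T`). Signature refitting solves the
non-negative least squares problem `min_{w≥0} ||c − S·w||₂` for a fixed
96×K reference matrix `S`; the HRD score is the SBS3 relative contribution
`w_SBS3 / Σw`. NNLS was chosen over cosine-similarity assignment because it
is the default strategy of the standard refitting tools and makes the
relative contribution scale-invariant by construction. HRD-high means a
relative contribution strictly above 0.05 (default) or 0.20 (the stricter
convention used for cohorts scored that way; both thresholds are exposed in
`HrdConfig` and no unification is attempted — the choice is
cohort-dependent).

The package ships a deterministic **synthetic reference signature matrix**
(`synthetic_signature_matrix`) with the qualitative shapes of SBS1 (C>T at
CpG), SBS2/SBS13 (APOBEC, C>T / C>G at TpC), SBS3 (near-flat) and SBS5
(broad, transition-tilted). It is a synthetic stand-in, not the COSMIC
matrix; any real 96×K signature TSV loads via
`ReferenceSignatures.from_tsv`. All refitting tests are round-trip
constructions against whichever matrix is supplied, so none of the package's
checks depend on true COSMIC entries.

**Copy-number-based.** The composite index is the unweighted sum
NtAI + LST + HRD-LOH of allelic-imbalance scar counts, HRD-high iff
strictly greater than 42. The three components are *inputs*: computing them
requires allele-specific copy-number segmentation, which is out of scope.

## TDP classification

The published TDP score is an external method whose formula this package
does not reproduce; a transparent substitute with the same role is provided
and its divergence is documented here. A genome is TDP when it carries at
least `min_td_count = 40` tandem duplications comprising at least
`td_fraction_min = 0.5` of its intrachromosomal rearrangements. Span modes
are located as local maxima of a Gaussian KDE (Scott's-rule bandwidth) of
log10 span, discarding peaks below 5% of the maximum density, and mapped to
short / medium / long bins at 100 kb and 1 Mb (`span_bin_edges`, exposed in
config; chosen to separate the short-span group that marks BRCA1
deficiency). TDP type 1 requires a short-span mode; remaining combinations
are labelled TDP "other" groups (group 2, group 3, mixes). Ties between
equal peaks resolve toward the shorter span, favouring type 1 sensitivity,
consistent with the use of TDP type 1 as the forensic marker of BRCA1 loss.
The exact span centers of the published groups 1/2/3 are not restated in the
sources this package follows; the bin edges are therefore configuration, not
constants.

## PDX response metrics

Each animal's growth rate is the OLS slope of natural-log tumor volume
versus day (≥ 3 strictly positive measurements required; invalid animals are
excluded with a log entry). The per-animal reduction is
`100 × (mean control slope − treated slope)` — each treated animal is
compared to the control-arm *mean*, and the model-level value is the mean
over treated animals. "5% reduction in growth rate" is implemented as an
absolute difference of 0.05 in the natural-log slope per day (reported as
percentage points): only this reading reproduces the stated equivalence to a
50% relative volume decrease over 14 days, `exp(−0.05×14) = 0.497`. The
relative reading (treated slope below 95% of control) would require an
implausible control growth rate near 1.0/day to produce the same volume
effect; it is rejected as the default but available via
`ResponseConfig(relative_reduction=True)`. Natural log (not log10/log2) for
the same reason.

Modified RECIST uses the percent volume change at the end of treatment
(day 28 for 4-week, day 21 for 3-week regimens; nearest measurement within
±3 days, since twice-weekly schedules rarely land exactly on the end day)
versus day 0: CR < −80, PR [−80, −30), SD [−30, 20], PD > 20. The stated
category intervals leave boundary values ambiguous in prose; the implemented
intervals place −80 in PR and −30 and +20 in SD, and the modal category over
replicate animals is the model call with ties broken toward the
less-responsive category (conservative responder calling). CR/PR models are
responders.

## Expression utilities

Upper-quartile normalisation divides each sample by the 75th percentile
(linear interpolation) of its nonzero values, rescaled by the cohort-mean
upper quartile; zero-count genes are excluded from the quantile. The
percentile-rank transform replaces each value by its fractional rank within
the sample, in (0, 1] with average ranks for ties (the 0–1 scale is a
package choice; only monotonicity matters downstream). ΔΔCt relative
expression is `2^−(ΔCt_sample − ΔCt_calibrator)` with ΔCt the mean target
minus mean housekeeping Ct over replicates; *SRP14* is the default
housekeeping gene but any identifier is accepted. DEG selection applies the
fixed thresholds p < 0.05 and |log2FC| > 1 (strict); the default test engine
is a plain Welch t-statistic on percentile-ranked values — the thresholds,
not the moderated-statistics machinery of the original analysis, are the
specified part, and the test engine is pluggable. Immune-gene enrichment is
a two-sided Fisher exact test on the DEG × immune 2×2 table.

## Combined response predictor and statistics

The decision tree is total over {BRCAmut, BRCA1meth, nonBRCA} ×
{M1 high, M1 low, M1 missing}: BRCAmut → responder; BRCA1meth →
non-responder; nonBRCA → responder iff M1 high; a nonBRCA sample with no M1
score is explicitly "unpredictable" (the single unpredictable cell), never a
silent default. The M1 split is strictly above the median of the nonBRCA
subset (midpoint convention for even n; the convention is a package choice).
When multiple cohorts are combined, each cohort's own nonBRCA median is
used.

Evaluation reports the outcome fraction in each predicted group, overall
accuracy over samples that have both a definite prediction and an outcome,
and the 2×2 table. Note that the published subgroup counts (16/19 responders
with pCR, 1/11 non-responders with pCR) imply an accuracy of 26/30 = 86.7%,
whereas the published overall accuracy is 81%; the basis of that 81%
(denominator or weighting) is not derivable from the printed counts, so the
reproducible surface is the subgroup fractions, which this package matches
exactly.

Statistical engines are library-backed behind the module surface: Fisher's
exact test (scipy; two-sided p by the "sum of probabilities ≤ observed"
rule, which reproduces the printed worked examples; the odds ratio reported
is the unconditional cross-product estimate), logistic association
(statsmodels binomial GLM with logit link, Wald z p-value, separation
flagged by an unavailable p), Cox proportional hazards (lifelines, with
optional strata and adjustment covariates), Mann-Whitney rank-sum
comparisons of the 22 immune-cell scores with Bonferroni correction over the
panel. The immune deconvolution provided is a simple NNLS fit of a bulk
profile against a cell-type signature matrix with fraction-normalised
weights and a relative-residual confidence flag — deliberately not the
original ν-SVR algorithm, whose scores are expected as inputs in normal use.

## Synthetic cohort generator

The generator's defaults are the study conditions of the cohorts it
emulates: a 42-tumor TNBC-trial-like cohort (9 BRCAmut / 11 BRCA1meth /
22 nonBRCA), pCR probabilities 8/9 (BRCAmut) and 3/11 (BRCA1meth), nonBRCA
pCR depending on the M1 score (0.75 above the nonBRCA median, 0.10 below —
chosen so the configured M1 effect is strong enough for the combined
predictor to separate from BRCA-only on cohorts of this size); PDX response
probabilities 10/11, 10/16 and 5/16 per group; complete methylation in
98–100% with partial methylation spanning 35.4–82.8% (11/16 complete);
PDX growth with control slope 0.08 ln-units/day, responder treatment
reduction 0.09 (placing responders well above and non-responders at 0.01
well below the 5-point threshold), lognormal measurement CV 0.1,
twice-weekly measurements over 28 days, three animals per arm.

Per-group SBS3 fractions are not published; the defaults (0.45 for the two
BRCA-deficient groups, 0.02 for nonBRCA) are free parameters chosen to sit
well clear of both the 5% and 20% calling thresholds. TD span profiles
default to a single short mode (median 11 kb, ~80 TDs) for BRCA-deficient
genomes and a sparse long-span profile (~10 TDs at 600 kb) for nonBRCA,
with a 12-event non-TD background — again clear margins on the classifier's
count/fraction/mode thresholds. Survival is exponential with hazard ratios
0.5 / 0.9 / 1.0 versus a 1100-day baseline median and uniform censoring
over 3000 days.

Methylation–expression coupling follows a multiplicative-silencing form on
the log scale: `log2 expr = baseline + log2(1 − 0.99·meth/100) + ε`, with
the Gaussian noise scaled so the signal share of the variance matches the
configured target correlation (default r = −0.82). Because the silencing
term is nonlinear in the methylation percentage, the recovered Pearson r is
attenuated slightly below the target (by a factor ≈ corr(meth, signal));
the recovery tolerance of ±0.1 at n = 200 absorbs this.

A single integer seed drives one fixed, named sub-stream per table
(`default_rng([seed, table_code])`), so adding a new table never perturbs
existing ones and `generate_outcome_cohort` (a lightweight
groups+M1+outcome generator used for repeated-cohort studies) produces
outcomes byte-identical to the full generator at the same seed.

**What the synthetic tests do and do not show.** The generator reproduces
the *statistical structure* the classifiers assume — group-conditional
spectra, span mixtures, methylation ranges, outcome frequencies, exponential
growth and survival — but not the complexities of real tumors: subclonal
mixtures, copy-number-driven spectra distortions, SV-caller artifacts,
batch effects, correlated immune programs, or non-proportional hazards.
Passing round-trip tests therefore demonstrates that the implementations
are correct and internally consistent at the configured effect sizes, not
that the classifiers achieve any particular accuracy on clinical data.

## Numerical choices and problem sizes

Refitting uses `scipy.optimize.nnls` (active-set; deterministic). KDE peak
picking evaluates the density on a 512-point grid padded 0.5 log10 units
beyond the span range. Growth fits use `numpy.polyfit` degree 1. Monte-Carlo
checks use 1,000 replicates; the predictor-dominance study uses 1,000
synthetic cohorts of 42 samples; parameter-recovery checks use n = 200
(correlation), n = 10,000 mutations (refit) and 500 per arm (Cox). These
sizes give stable estimates at the stated tolerances while keeping the full
suite fast on a single CPU.

## Known limitations

- The TDP rule is a documented substitute for the published score, not a
  reimplementation of it; concordance with published TDP calls on real
  genomes is not guaranteed, only the role of the classifier in the
  pipeline.
- NtAI/LST/HRD-LOH computation, de novo signature extraction, variant
  pathogenicity interpretation, RSEM quantification, transcriptional
  subtyping and the ν-SVR deconvolution are all out of scope; their outputs
  are inputs here.
- The cellularity-correction formula and several boundary conventions
  (threshold inclusivity, RECIST boundaries, median convention) are package
  choices where the source procedures are silent; all are exposed in config
  and documented above.
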