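# Methods

## Analysis model

The package operationalizes a three-step methodology for studying language
impairment in Alzheimer's disease (AD) from spontaneous picture
descriptions across two languages:

1. extract an identical feature set per subject in each language cohort;
2. screen every feature per language with a nonparametric group test and
   keep, as *generalizable*, the non-task features significant
   (uncorrected p < 0.05) in **both** languages;
3. compare classifiers trained on all language features vs. only the
   generalizable set, in each language and in the pooled multilingual
   cohort, under leave-one-out cross-validation (LOOCV).

The premise is that features that discriminate AD from controls in two
unrelated corpora and languages are more likely to measure the
neurocognitive construct (language impairment) than corpus idiosyncrasies.

## Transcript ingestion

CHAT documents are reduced to the participant tier (`*PAR`). Annotation is
stripped deterministically: timing bullets, paralinguistic event codes
(`&=...`), phonological fragments (`&+...`), and all bracketed codes
(retracing `[/]`, `[//]`, comments) are removed while the retraced words
themselves are kept; shortenings like `(be)cause` expand; filled pauses
(`&-uh` → "uh") are kept as word tokens (a flag excludes them from word
counts). Unintelligible markers (`xxx`, `yyy`, `www`) are dropped. A tier
line holding several sentences is split at utterance terminators, so
sentence counts equal utterance counts. These normalization rules favor
maximal retained speech content and bit-reproducibility; they are not the
only defensible choice, and the parser is deliberately small and auditable.

## Information-unit lexicon and matching

Sixteen IUs (boy, girl, woman, kitchen, exterior, cookie, jar, stool, sink,
plate, dishcloth, water, window, cupboard, dish, curtain) each map to a set
of synonymous keywords per language ("boy" may be said as *brother* or
*son*), with region assignments under three divisions of the picture
(halves, quadrants, vertical stripes). The shipped JSON configs are
editable defaults: the spatial assignments follow the conventional scene
layout (boy/girl/jar/stool/cupboard on the left; woman/sink/window/... on
the right) and can be replaced wholesale.

Matching is case-insensitive on surface forms with a small per-language
inflection table (English -s/-es/-ies plurals; French -s/-x), longest match
first so "cookie jar" beats "cookie", non-overlapping so nothing is
counted twice. Lemma-level matching via a tagger is deliberately not the
default: surface matching is reproducible with no model downloads, and the
inflection table covers the overwhelming share of picture-description
forms.

## Text features

- **Task-specific (89)**: per IU, a mention indicator, a count, and the
  share of all mentions; per region and division, keyword token count,
  keyword TTR, keyword-to-word ratio, and the fraction of the region's IUs
  mentioned ("percent uttered" is IU-based, a documented choice since a
  word-based reading is also possible); plus the number of left/right
  switches in mention order.
- **Semantic (25)**: the IU summary block (unique/total counts, densities
  by word count, keyword-to-non-keyword ratio k/(N−k), inventory coverage
  /16, keyword TTR, and per-second efficiencies which require a response
  duration); mean/median/max word frequency and word length over all words
  and over mentioned keywords; TTR; MATTR with window 10 (texts shorter
  than the window fall back to plain TTR). Word frequencies come from a
  packaged per-language relative-frequency table; any two-column CSV can be
  substituted. Note one naming subtlety: the word-count-normalized variant
  of unique-keyword coverage is registered as `unique_keyword_density`, so
  that `unique_IU_efficiency` unambiguously names the duration-normalized
  feature — a registry cannot hold one name for two definitions.
- **Syntactic (44)**: sentence count, word count, mean words per sentence;
  per-UPOS counts and ratios (denominator = word count excluding
  punctuation, except `PUNCT_ratio` whose denominator is all tokens);
  noun/verb, pronoun/noun, determiner/noun and open/closed class ratios;
  mean/median/max absolute head distance over non-root, non-punctuation
  tokens.

Tagging and head assignment sit behind a one-callable backend contract.
The packaged default is a deterministic lexicon tagger (word-list lookup,
unknown → NOUN, fillers → INTJ) with a rule head-assigner (first verb is
root; determiners/adjectives attach to the next noun; everything else to
the root). It tags the synthetic cohorts' controlled vocabulary exactly and
keeps CI free of model downloads; for real transcripts a pretrained tagger
should be adapted to the same contract.

The family sizes above are what the registry actually contains and are
exposed programmatically (`registry_counts`); published family counts for
analyses of this kind vary with exactly which variants are included, so the
registry is the source of truth here.

## Paralinguistic features (209)

All audio is resampled to 16 kHz mono. Frames are 25 ms at a 10 ms step
(conventional defaults; fixed in module constants).

- **Temporal (7)**: syllable nuclei are intensity peaks ≥ 2 dB above their
  surrounding dips and above a silence threshold (25 dB below peak
  intensity); speaking intervals are sounding-frame runs with gaps shorter
  than 0.3 s bridged. From these: syllable count, total and speaking
  duration, speech rate (syllables/total), articulation rate
  (syllables/speaking), speaking ratio, and a pronunciation score defined
  here as the percentage of nuclei falling in voiced frames (the
  posterior-probability score of the tool that inspired this block is
  proprietary to that tool; the voiced-nuclei fraction is this package's
  documented stand-in).
- **F0 (6)**: normalized-autocorrelation pitch per 40 ms frame, floor
  75 Hz, ceiling 500 Hz, voicing threshold 0.45; mean, SD, min, max and
  quartiles over voiced frames.
- **MFCC (168)**: pre-emphasis 0.97, Hamming window, 512-point rfft power
  spectrum, 26 triangular mel filters, log energies, orthonormal DCT-II,
  14 coefficients (coefficient 0 is registered as `energy`); velocity and
  acceleration are first and second frame differences; per series the
  mean, variance, skewness and excess kurtosis. Zero-variance series
  report 0 shape moments rather than NaN so degenerate clips do not
  poison downstream models.
- **Spectral (28)**: RMS, spectral centroid, bandwidth, flatness,
  zero-crossing rate (counted on a whole-signal crossing indicator and
  framed, which keeps the estimate unbiased for tonal signals), loudness
  (frame energy in dB) and spectral flux; mean/max/min/SD each.

Scale invariances hold where mathematically implied (F0, ZCR, centroid,
flatness are unchanged under constant amplitude scaling), and extraction is
bit-deterministic.

## Screening statistics

Per feature and language: tie-corrected Kruskal–Wallis H (two groups, so H
~ χ² with df = 1 under the null), raw p, Bonferroni-adjusted p = min(1,
p·m), group means, and the point-biserial correlation r_pb (Pearson r
against the AD=1 indicator) as a cross-language comparable effect size.
Choices:

- the Bonferroni multiplier m defaults to the number of features actually
  screened at runtime, with an override for mirroring an externally fixed
  test count (e.g. 377);
- correction is applied within each language independently, so each feature
  carries four significance values (p and adjusted p per language);
- selection uses **uncorrected** p < 0.05 in both languages, strict
  inequality, task features excluded by definition;
- missing values are dropped per feature (pairwise deletion), maximizing
  usable data; rows with fewer than 2 values per group keep their slot with
  missing statistics;
- an all-tied feature reports H = 0, p = 1.

## Classification protocol

Models: logistic regression (L2, C = 1), SVC (RBF, C = 1), MLP (one hidden
layer of 100 units, logistic activation, alpha = 0.01, seeded); no
hyperparameter tuning anywhere. The LR iteration cap is raised to 2000 —
a numerical-convergence choice, not a tuned hyperparameter.

LOOCV holds out each subject once. Per fold, missing values are imputed
with training-fold medians, fold-constant features dropped, and features
standardized to training-fold mean 0/SD 1 — preprocessing is fitted
strictly on the training fold (a leakage test poisons a held-out value and
asserts the score is unchanged). Scores are `predict_proba` for LR/MLP
(hard threshold 0.5) and the SVM margin (threshold 0). AUC is computed
once from the pooled held-out scores as the normalized Mann–Whitney U
(ties count 1/2): with one test sample per fold a per-fold AUC is
undefined, so pooling is the only well-defined reading of an averaged
LOOCV score.

Feature selection is, by default, computed on the full cohort before LOOCV
— faithful to the analysis design this package implements, which selects
features once from the complete data; a nested mode re-selecting within
each training fold is the statistically honest alternative and is exposed
as a config option (`mode="nested-selection"`).

The scenario grid is {EN, FR, multilingual} × {all language features,
generalizable features} plus an English all-subgroups baseline and a
multilingual age-only baseline: 8 scenarios × 3 models = 24 runs.
"Language features" are semantic ∪ syntactic ∪ paralinguistic. The
multilingual cohort is a row concatenation of the two language cohorts; the
language tag is never a model input, only the key for the per-language
confusion decomposition (error rate in percent; a language's
false-positive share is FP/(FP+FN) of that language's errors).

## Synthetic cohorts

The generator emulates the statistical structure reported for real AD/HC
picture-description cohorts, not natural discourse:

- each of the 16 IUs is mentioned with per-group probability (HC 0.7, AD
  0.4) and realized as a templated sentence whose verb phrase contains no
  keywords, so each sentence adds exactly one keyword mention;
- specific synonyms ("brother" rather than "boy") are chosen with
  probability 0.5 (HC) vs 0.2 (AD); repeated mentions substitute a pronoun
  with probability 0.1 vs 0.35; fillers are inserted at 0.05 vs 0.15;
- response durations are lognormal with AD shorter (medians ≈ 60 s HC vs
  ≈ 45 s AD, in the range of real picture-description recordings); ages
  are Gaussian per language and group, with the French cohort older and
  group-unbalanced (a realistic confound the age-only baseline probes);
- paralinguistic rows are drawn from language-specific unit Gaussians with
  standardized group shifts only for configured (feature, language) pairs;
  the defaults plant two bilingual effects (speaking ratio −0.8, speech
  rate −0.6) and six single-language effects, mirroring the reported weak
  cross-language overlap of acoustic features.

Every planted effect is declared in a `GroundTruth` map as (languages,
sign, approximate standardized magnitude). Magnitudes for text features
are design values implied by the parameter gaps — the mention-rate gap
moves IU counts by roughly two within-group SDs, while
`unique_IU_efficiency` is intentionally diluted (fewer IUs but also less
time) and declared at 0.5. Recovery guarantees in the acceptance suite
therefore apply to strongly planted (|d| ≥ 0.8) bilingual effects, which
is also the regime where a rank test at n = 50/group has the power to make
a ≥ 90% joint selection rate attainable at all.

What passing these tests shows — and does not show: the pipeline correctly
recovers effects of the declared structure from data that satisfy its
assumptions (independent subjects, unimodal feature distributions,
template-clean transcripts, exactly tagged tokens). Real transcripts bring
disfluency, ASR or transcription noise, tagger errors and correlated
features; results on synthetic cohorts bound implementation correctness,
not clinical performance.

## Problem sizes and numerical choices

Simulation-backed guarantees run at the scales stated with them: type-I
calibration uses 1000 null features at n = 50/group (acceptance band:
0.05 ± the 99% binomial interval half-width, ±0.018, fixed a priori);
selection recovery averages 100 seeded cohorts at n = 50/group/language;
permutation-null AUC averages 20 label permutations at n = 100. The full
24-run scenario grid is exercised structurally on cohorts of
8/group/language — structure (run count, matrix additivity), not
performance, is what that check certifies.

Degenerate inputs are mapped to explicit values rather than exceptions
where a value is defensible (empty mention set → zero densities; all-word
keywords → missing ratio with a warning; silent audio → zero syllables and
missing articulation rate; all-tied feature → H = 0, p = 1) and to errors
where silence would corrupt an analysis (single-class training fold,
mismatched feature universes between languages, unknown language tags).

## Known limitations

- The default tagger is a word-list heuristic: adequate for the synthetic
  vocabulary and coarse on real speech; swap in a pretrained tagger via the
  backend contract for real corpora.
- Examiner speech is not separated from audio (no diarization), matching
  common practice with whole-session recordings.
- The packaged frequency tables are small defaults, not a corpus-scale
  resource.
- No FDR or other multiplicity alternatives in the default path; Bonferroni
  only, by design.
- LOOCV with full-data feature selection overstates generalization; use
  nested mode for honest estimates.
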