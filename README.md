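# speechmarkers

Multilingual spontaneous-speech markers of Alzheimer's-related language
impairment from Cookie-Theft picture descriptions.

Clinicians elicit spontaneous speech with the Cookie Theft picture from the
Boston Diagnostic Aphasia Examination and score how many of its content
elements — *information units* (IUs) such as the boy, the cookie jar, the
overflowing sink — a patient mentions. `speechmarkers` automates and extends
this analysis for researchers working on speech-based dementia screening in
more than one language. It provides:

1. **Feature extraction** from CHAT-format transcripts and (optionally) WAV
   audio, in four registered families:
   - *task-specific*: per-IU mention indicator/count/share and spatial
     coverage of the picture (halves, quadrants, vertical stripes),
   - *semantic*: IU summaries (e.g. unique-IU density `num_unique_IU / word
     count`, keyword-to-non-keyword ratio `k / (N − k)`, IU efficiency
     `mentions / response seconds`), word frequency/length statistics, TTR
     and the moving-average type-token ratio (MATTR, window 10),
   - *syntactic*: sentence statistics, Universal-POS counts and ratios,
     open/closed class ratio, dependency-length summaries,
   - *paralinguistic*: syllable-nuclei timing measures, F0 statistics,
     summary moments of 14 MFCCs and their Δ/ΔΔ, and spectral descriptors
     (209 features).
2. **Cross-language screening**: per-language Kruskal–Wallis H tests
   (χ², df = 1) with Bonferroni adjustment and point-biserial effect sizes
   r_pb; a feature is *generalizable* when its uncorrected p < 0.05 in both
   English and French and it is not task-specific.
3. **Evaluation**: leave-one-out cross-validated AD-vs-HC classification
   (L2 logistic regression, RBF SVM, MLP) over an 8-scenario × 3-model
   grid, with pooled AUC and per-language confusion-matrix decomposition.
4. **A synthetic bilingual cohort generator** with declared ground-truth
   effects, so the entire pipeline is testable without access-restricted
   clinical corpora.

## Worked example

The semantic extractor on a minimal description (`examples/01_worked_example.py`):

```text
word count: 18
mentions: [('boy', 'boy'), ('boy', 'boy'), ('brother', 'boy'),
           ('cookie', 'cookie'), ('sister', 'girl')]
  num_unique_IU                        3.0000
  num_unique_keywords                  4.0000
  num_total_keywords                   5.0000
  unique_IU_density                    0.1667
  total_IU_density                     0.2778
  keyword_to_non_keyword_ratio         0.3846
  unique_keyword_density               0.2222
  percentage_of_keywords_mentioned     0.1875
  keyword_TTR                          0.8000
  total_IU_efficiency                  0.3333
  unique_IU_efficiency                 0.2000
```

Three unique IUs (boy, cookie, girl) were realized by four distinct
keywords across five mentions in 18 words: unique-IU density 3/18 = 0.1667,
keyword-to-non-keyword ratio 5/(18−5) = 0.3846, and with a 15 s response,
5/15 = 0.33 keyword mentions per second.

The other examples generate a synthetic cohort, run the screening/selection
step, execute the full classification grid, and extract audio features from
synthesized signals:

```bash
python examples/02_synthetic_cohort.py
python examples/03_screening_and_selection.py
python examples/04_classification.py
python examples/05_audio_features.py
```

A shell interface wraps the same API:

```bash
speechmarkers simulate --n 20 --seed 1 --out synth/
speechmarkers run-all --out run/ --seed 1
```

`run-all` writes `features.csv`, `registry.csv`, `stats.csv`,
`selection.json`, `results.json` and a readable `report.md`, all embedding
the seed and config hash.

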