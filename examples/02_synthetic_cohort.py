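"""Generate a synthetic bilingual cohort and inspect the planted effects.

The generator draws HC and AD picture descriptions in English and French
with group-dependent information-unit coverage, lexical specificity,
pronoun substitution and response duration.  The printed group means show
the AD group mentioning fewer IUs in both languages — the planted
semantic deficit.
"""

import pandas as pd

from speechmarkers import (SynthParams, extract_cohort_features,
                           generate_cohort)

params = SynthParams(n_per_group_per_language=30, seed=42)
records, labels, ground_truth = generate_cohort(params)
features, registry = extract_cohort_features(records)
languages = pd.Series({r.subject_id: r.language for r in records})

print(f"{len(records)} subjects, {features.shape[1]} text features")
print("\nplanted bilingual effects:",
      sorted(ground_truth.bilingual_features()))

for lang in ("en", "fr"):
    sub = features.loc[languages == lang]
    grp = labels[languages == lang]
    print(f"\n[{lang}] group means:")
    for name in ("num_unique_IU", "word_count", "PRON_ratio"):
        m_hc = sub.loc[grp == "HC", name].mean()
        m_ad = sub.loc[grp == "AD", name].mean()
        print(f"  {name:24s} HC={m_hc:7.3f}  AD={m_ad:7.3f}")
print("\nLower AD means for IU counts in both languages reflect the "
      "generated semantic impairment; the higher AD pronoun ratio "
      "reflects pronoun substitution for forgotten nouns.")
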