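"""Cross-language screening and generalizable-feature selection.

Each feature is tested per language with a Kruskal-Wallis H test; features
with uncorrected p < 0.05 in BOTH English and French (excluding
task-specific features) form the generalizable set — markers of language
impairment that are not corpus- or language-specific.
"""

import pandas as pd

from speechmarkers import (SynthParams, extract_cohort_features,
                           generate_cohort, generate_paralinguistic_table,
                           build_stats_table, select_generalizable)
from speechmarkers.xlingual import stats_to_frame

params = SynthParams(n_per_group_per_language=50, seed=7)
records, labels, gt = generate_cohort(params)
features, registry = extract_cohort_features(records)
para = generate_paralinguistic_table(params, records)
features = features.join(para)
registry.update({c: "paralinguistic" for c in para.columns})
languages = pd.Series({r.subject_id: r.language for r in records})

stats = {}
for lang in ("en", "fr"):
    sel = languages == lang
    stats[lang] = build_stats_table(features.loc[sel], labels[sel], lang,
                                    registry=registry)

result = select_generalizable(stats["en"], stats["fr"], registry)
print(f"screened {features.shape[1]} features per language")
print(f"selected {len(result.selected)} generalizable features "
      f"(alpha={result.alpha}, {result.excluded_task_count} task features "
      "excluded by rule):")
for name in sorted(result.selected):
    print(f"  {name} ({registry[name]})")

frame = stats_to_frame(stats["en"])
top = frame.nsmallest(5, "p")[["feature", "r_pb", "m_HC", "m_AD", "H", "p"]]
print("\nstrongest English effects (negative r_pb = lower in AD):")
print(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
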