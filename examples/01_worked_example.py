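"""Semantic scoring of a single Cookie-Theft description.

Parses a short CHAT-format description, matches information-unit (IU)
keywords with the default English lexicon, and prints the semantic summary
features.  With 5 keyword mentions over 18 words and a 15 s response, the
densities show how much of the utterance carries picture content and the
efficiencies how quickly content is produced.
"""

from speechmarkers import (iu_summary_features, load_lexicon, match_mentions,
                           parse_chat, word_count)

DOC = ("*PAR:\tThere is a boy . The boy is a brother . "
       "He is stealing a cookie . The sister is watching .")

lexicon = load_lexicon(language="en")
transcript = parse_chat(DOC)
mentions = match_mentions(transcript, lexicon)

print(f"word count: {word_count(transcript)}")
print("mentions:", [(m.keyword, m.iu_name) for m in mentions])

fv = iu_summary_features(mentions, word_count(transcript), 15.0, lexicon)
for name, value in fv.values.items():
    print(f"  {name:36s} {value:.4f}")
print("\nunique_IU_density = unique IUs / words; total_IU_efficiency = "
      "keyword mentions per second of response.")
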