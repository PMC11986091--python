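"""Closed-loop evaluation on a synthetic gold-labeled corpus.

Generates a seeded toy dictionary set and a 300-entry corpus with known
gold annotations, standardizes the corpus, and prints the three-bucket
evaluation report (entry level and token level).  With no injected typos
the pipeline must recover every gold record, so all success rates read
100.0%.
"""

from atcmap import SyntheticConfig, build_fixture_set, evaluate, standardize

atc, rad, stoplist, corpus = build_fixture_set(
    SyntheticConfig(n_entries=300, typo_rate=0.0)
)
records = standardize(corpus.entries, atc, rad, stoplist)
outcomes, summary = evaluate(records, corpus.gold_annotations)

print(summary.to_text())
print()
print(f"gold records recovered exactly: "
      f"{sum(r == g for r, g in zip(records, corpus.gold_records))}/{len(records)}")
print("Every entry and every expected token lands in the success bucket;")
print("the additional-information count tallies entries with Study/Info content.")
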