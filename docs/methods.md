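# Methods

## The standardization model

`atcmap` is a deterministic, dictionary-based entity-standardization
pipeline. Its target vocabulary is the WHO ATC classification: five
hierarchical levels, 14 anatomical main groups at level 1, and a
7-character level-5 code shaped letter / 2 digits / 2 letters / 2 digits.
Chapter `L` (antineoplastic and immunomodulating agents) is the domain
focus and drives both the column split of the output and the multi-code
resolution rule.

The core assumptions are:

- each input row is one administration event whose medication content is
  expressible as 1–n substance/regimen tokens plus disposable context
  (dose, route, timing);
- dictionary lookup is **exact** after normalization — there is no fuzzy
  or edit-distance matching, so unknown misspellings fail by design and
  surface as residual tokens for dictionary refinement;
- dosage and administration route carry no information for the target
  representation and are deliberately discarded.

## Normalization and tokenization

Transliteration maps ä/ö/ü/ß to ae/oe/ue/ss. The uppercase forms Ä/Ö/Ü/ẞ
map to AE/OE/UE/SS: transliteration runs before uppercasing and clinical
text contains capitalized words, so dropping them would leave non-ASCII
tokens. The mapping is idempotent (property-tested).

Hyphens are deleted *without* splitting the token (`5-FU` → `5FU`):
splitting would destroy abbreviation identity, and RAD keys are stored
hyphen-free accordingly. Every other non-alphanumeric character is a
delimiter. Decimal commas therefore split `1,5` into two numeric tokens;
both are stoplist noise, an acceptable loss since dosage is discarded
anyway.

The shipped stoplist is a documented starting list, not a claim of
completeness: unit literals (MG, ML, G, IE), time literals (TAG, TAGE,
WOCHE, ZYKLUS, TAEGLICH) and the patterns `^\d+$` and `^\d+[A-Z]{1,3}$`
for bare numbers and number+unit fusions. It is editable as a TSV.
**Dictionary membership beats the stoplist**: a token equal to a RAD or
ATC key is never removed (otherwise `5FU` would be eaten by the
number-prefix pattern). Conflicts between stoplist and dictionaries are
detected when a pipeline is assembled and reported as warnings.

## Dictionary semantics

Keys and patterns pass through exactly the normalization applied to input
text, so matching is a string comparison. The default is exact equality;
an entry may opt into glob matching with `*` (matching zero or more of
`[A-Z0-9]`). Globs are opt-in per entry rather than the default because
silent prefix matching on medication names risks false merges.

RAD keys may be multi-token phrases ("BEST SUPPORTIVE CARE"); phrase keys
are matched longest-first at each position before single-token lookup.
RAD targets are exactly one of: EXPANSION (≥1 substance names), STUDY,
INFO, or MEDICATION (a recognized name with no ATC code). Expansion
payloads are cross-checked against the ATC dictionary at load time;
unresolvable names are warnings, not errors.

Structurally invalid codes in a user-supplied ATC dictionary are kept
with a warning (real registries contain pseudo-codes; downstream routing
only inspects the first letter); `strict_codes` upgrades them to errors.
One deliberate consequence: the six-character string `M01CX0` is
classified invalid by the validator yet flows through resolution
unchanged, because resolution never validates.

## Resolution and assembly

Resolution is applied **per token** (per substance), then the entry's
resolved codes are merged: among several candidate codes the
lexicographically smallest `L` code wins; with no `L` code, the
alphabetically smallest code overall. The lexicographic tie-break among
multiple `L` codes is this package's choice, consistent with the
alphabetical fallback. Code columns are deduplicated and sorted
ascending; empty cells serialize as empty strings; multi-value cells are
joined with a configurable joiner (default `", "`). Residual tokens stay
in memory (and in the log) for evaluation and dictionary refinement but
are not part of the exported table.

## Evaluation taxonomy

Against gold annotations, every entry lands in exactly one bucket:
*successfully transformed* (all expected transformations present), *error
in transformation* (≥1 expected transformation missing anywhere in the
output), or *no useful information* (nothing expected, nothing produced).
Token-level rates count only tokens expected to yield an ATC code;
no-useful-information entries contribute one token each to the token
table; Study/Info extraction is reported separately as the count of
entries with additional information. Rates are percentages rounded to one
decimal. Aggregation is two-path consistent (summing per-entry outcomes
equals direct aggregation; property-tested).

## Synthetic fixtures

The real ATC index (WIdO) is licensed and clinical corpora are not
public, so testing runs against generated stand-ins:

- **Toy ATC dictionary** — invented pronounceable names (suffixes -MAB,
  -PLATIN, -TINIB… give realistic length variety; no real drug names, so
  no overlap with licensed data) with structurally valid, unique level-5
  codes, ~70% in chapter L to reflect an oncology registry; one name
  always carries an L and a non-L code so resolution is always exercised.
- **Toy RAD** — regimen acronyms expanding to 2–3 substances, prefix
  truncations and hyphenated `5-<NAME>` aliases, the study terms
  (Studie, Register, Protokoll), info terms (TACE, Chemotherapie,
  Erhaltungstherapie), one phrase key and one MEDICATION key.
- **Corpus** — each entry carries one regimen (default 25%) or 1–4
  substances in varied casing, optionally an abbreviation or
  "alias (Fullname)" parenthetical, plus dose strings (40%), study
  markers (15%) and info words (15%), mixed separators and occasional
  trailing punctuation. Gold annotations and gold records derive from
  the generative choices only, never from the pipeline under test.

Typos are modeled solely as a single adjacent-letter transposition — the
data-entry error that defeats exact lookup — applied per written
substance token (or regimen acronym) with probability `typo_rate`; the
corrupted token is verified unknown to both dictionaries and to the
stoplist, and all gold tokens it should have produced are marked
expected-to-fail. Corrupting an acronym fails all of its expansion
tokens, so the marginal token failure probability still equals
`typo_rate`, with mild clustering.

What passing closed-loop tests shows: the pipeline inverts its own
generative model exactly (tokenization, expansion, dedup, resolution,
routing are lossless on well-formed input). What it does not show:
coverage of real German clinical vocabulary, real misspelling
distributions, or real dictionary quality — those live in the user's
dictionaries, not in this code.

Defaults: seed 20250410 (all randomness flows from the single config
seed; CI is reproducible), 500 entries, 50 substances, 8 regimens. The
acceptance script uses 500 clean entries and 2000 typo-bearing entries —
sizes at which a binomial 99% interval around the injection rate is a few
tenths of a percentage point wide while the full run stays in seconds.

## Numerical and interface choices

- Ties and ordering everywhere are lexicographic on uppercase ASCII, so
  serialized output is byte-stable across runs.
- Deduplication keeps first occurrence and is idempotent.
- Encoding is UTF-8 in and out (BOM tolerated on input); other encodings
  are rejected, not guessed. File writes are atomic (temp + rename).
- The CLI accepts multi-column tables and standardizes the named/first
  column — a pragmatic superset of the single-column contract.
- Empty inputs are well-defined: empty table → header-only output; empty
  token sequence → all-empty record; empty evaluation → null rates.

## Known limitations

No fuzzy recovery of residuals; German-specific normalization only; no
dosage/route extraction; no ATC level-1–4 rollups or DDD handling; the
phrase matcher is greedy longest-first (no backtracking across
overlapping phrase keys); synthetic corpora make no claim of statistical
realism about prescription frequencies or grammar.
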