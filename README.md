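# atcmap

Dictionary-based standardization of German free-text medication entries
into WHO **ATC** (Anatomical Therapeutic Chemical) codes, with a focus on
oncology documentation.

Clinical records in German-speaking tumor documentation routinely carry
medication as free text — substance names, regimen acronyms (FOLFOX),
abbreviations ("5-FU"), doses, umlauts, study markers — which blocks any
systematic analysis of treatment patterns. `atcmap` turns one column of
such text into a structured table deterministically, using two curated
dictionaries instead of any learned model, so every transformation is
auditable and correctable.

## Method

For each entry:

1. **Normalize** — transliterate umlauts/eszett (ä→ae, ö→oe, ü→ue, ß→ss),
   split into tokens with punctuation and symbols as delimiters (hyphens are
   deleted *in place*, so `5-FU` → `5FU`), uppercase, and drop noise tokens
   (units, time words, numbers, number+unit fusions) via an editable
   stoplist. A token that equals a dictionary key is never dropped.
2. **RAD stage** — match tokens (longest phrase first) against the
   regimens-and-abbreviations dictionary: regimen acronyms expand to their
   constituent substance names, study/info/medication terms are routed to
   side channels, and the expanded sequence is deduplicated entry-wide
   (`5-FU (Fluorouracil)` yields one Fluorouracil token).
3. **ATC stage** — each remaining token collects its candidate code set
   from the ATC dictionary (exact match by default; per-entry `*` globs).
4. **Resolve** — a token with several codes keeps the lexicographically
   smallest code starting with `L` (antineoplastic priority); with no `L`
   code, the alphabetically first code wins.
5. **Assemble** — codes are split by first letter into
   `AntineoplasticMedication` (`L…`) and `AdditionalMedication` (other
   chapters); recognized code-less names, study terms and supplementary
   info fill `Medication`, `Study` and `Info`. Unmatched residual tokens
   are logged (they drive dictionary refinement) but never exported.

A full level-5 ATC code is one letter (one of the 14 anatomical groups),
two digits, two letters, two digits — e.g. `L01BA01` with hierarchy
prefixes `L`, `L01`, `L01B`, `L01BA`, `L01BA01`.

The licensed WIdO ATC index is **not** bundled. A synthetic-fixture module
generates structurally faithful toy dictionaries and gold-labeled corpora
(invented substance names, valid codes, regimen acronyms, typo injection)
so the whole pipeline and its evaluation are testable end to end; bring
your own dictionary TSVs for production use.

## Worked example

`python examples/standardize_basic.py` prints:

```
     Medication_text AntineoplasticMedication AdditionalMedication Medication  Study Info
         Methotrexat                  L01BA01                                            
 5-FU (Fluorouracil)                  L01BC02                                            
FOLFOX 100mg täglich         L01BC02, L01XA03              V03AF03                       
  Cisplatin + Studie                  L01XA01                                 Studie     
```

Methotrexat carries two codes (`L01BA01`, `M01CX0`) and resolves to the
antineoplastic one; the abbreviation plus its parenthetical expansion
deduplicate to a single Fluorouracil mapping; FOLFOX expands to three
substances whose codes split across the two code columns; dose and time
tokens are discarded and `Studie` lands in the Study column. (The run also
warns that the stoplist's number-prefix pattern would match the dictionary
key `5FU` — dictionary membership wins.)

## Command line

```sh
atcmap make-fixtures --target fixtures/ --n-entries 100
atcmap standardize --input fixtures/entries.csv --output out.csv \
    --atc fixtures/atc.tsv --rad fixtures/rad.tsv --stoplist fixtures/stoplist.tsv
atcmap evaluate --input fixtures/entries.csv --gold fixtures/gold.tsv \
    --atc fixtures/atc.tsv --rad fixtures/rad.tsv --report-json report.json
atcmap validate-dicts --atc fixtures/atc.tsv --rad fixtures/rad.tsv
```

`evaluate` reports the three-way outcome taxonomy at entry and token level
— successfully transformed / error in transformation / no useful
information — plus the count of entries with extracted Study/Info content.

## File formats

- **ATC dictionary TSV**: columns `code`, `name`, `pattern` (pattern
  optional, defaults to the normalized name); `#` comments.
- **RAD TSV**: columns `key`, `kind` ∈ {EXPANSION, STUDY, INFO,
  MEDICATION}, `payload` (semicolon-separated names for EXPANSION).
- **Stoplist TSV**: columns `kind` ∈ {LITERAL, PATTERN}, `value`.
- A YAML nested-list dialect is accepted as an alternative dictionary
  format (`load_atc_dictionary_yaml`, `load_rad_yaml`).

All files are UTF-8; input tables may be CSV or TSV.
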