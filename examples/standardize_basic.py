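"""Standardize a handful of free-text entries with small in-code dictionaries.

Builds a minimal ATC dictionary and RAD, runs the full pipeline on four
typical free-text forms (plain name, multi-code substance, abbreviation with
parenthetical, regimen acronym plus noise), and prints the six-column output
table.  The AntineoplasticMedication column holds resolved chapter-L codes;
AdditionalMedication holds everything else; dosage tokens are discarded.
"""

from atcmap import (
    AtcDictionary,
    RadKind,
    RadTarget,
    RawEntry,
    RegimenDictionary,
    default_stoplist,
    records_to_frame,
    standardize,
)

atc = AtcDictionary()
atc.add("Methotrexat", "L01BA01", name="Methotrexat")
atc.add("Methotrexat", "M01CX0")  # second, non-antineoplastic code
atc.add("Fluorouracil", "L01BC02", name="Fluorouracil")
atc.add("Calciumfolinat", "V03AF03", name="Calciumfolinat")
atc.add("Oxaliplatin", "L01XA03", name="Oxaliplatin")
atc.add("Cisplatin", "L01XA01", name="Cisplatin")

rad = RegimenDictionary()
rad.add("5-FU", RadTarget(kind=RadKind.EXPANSION, names=("FLUOROURACIL",)))
rad.add("FOLFOX", RadTarget(kind=RadKind.EXPANSION,
                            names=("FLUOROURACIL", "CALCIUMFOLINAT", "OXALIPLATIN")))
rad.add("Studie", RadTarget(kind=RadKind.STUDY, term="Studie"))

entries = [
    RawEntry("E00001", "Methotrexat"),
    RawEntry("E00002", "5-FU (Fluorouracil)"),
    RawEntry("E00003", "FOLFOX 100mg täglich"),
    RawEntry("E00004", "Cisplatin + Studie"),
]

records = standardize(entries, atc, rad, default_stoplist())
frame = records_to_frame(records)
print(frame.to_string(index=False))
print()
print("Methotrexat resolves to its L code only; FOLFOX expands to three")
print("substances (two L codes, one V code); dose/time tokens are dropped;")
print("'Studie' is routed to the Study column instead of a code column.")
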