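"""Synthetic toy dictionaries and gold-labeled corpora for closed-loop testing.

The real ATC dictionary (WIdO) is licensed and the clinical evaluation data
are not public, so this module generates structurally faithful stand-ins:

* a toy ATC dictionary of invented, pronounceable substance names (suffixes
  like -MAB, -PLATIN, -TINIB give realistic length variety; no real drug
  names) with structurally valid level-5 codes, ~70% in chapter 'L', and at
  least one name carrying two codes (one 'L', one not) to exercise
  multi-code resolution;
* a toy RAD with regimen acronyms expanding to 2–3 substances, abbreviation
  keys (prefix truncations, hyphenated aliases such as "5-<NAME>"), the
  study indicator terms (Studie, Register, Protokoll) and info terms
  (TACE, Chemotherapie, Erhaltungstherapie);
* free-text entries of 1–4 substances or one regimen, decorated with doses,
  umlaut-bearing time words, study/info markers and punctuation, each with
  a gold annotation and a gold standardized record **derived from the
  generative choices only** — never from the pipeline under test.

Typos are modeled as a single adjacent-letter transposition (the data-entry
error type that defeats exact dictionary lookup); a corrupted surface token
is guaranteed unknown to both dictionaries, and every gold token it was
expected to produce is marked expected-to-fail.

All randomness flows from the single seed in :class:`SyntheticConfig`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .dictionaries import (
    VALID_FIRST_LETTERS,
    AtcDictionary,
    RadKind,
    RadTarget,
    RegimenDictionary,
)
from .evaluation import GoldAnnotation, write_gold_tsv
from .pipeline import StandardizedRecord
from .preprocess import RawEntry, Stoplist, default_stoplist, normalize_key

__all__ = [
    "DEFAULT_SEED",
    "SyntheticConfig",
    "SyntheticCorpus",
    "build_toy_atc",
    "build_toy_rad",
    "generate_entries",
    "build_fixture_set",
    "write_fixture_dir",
]

#: Fixed default seed so shipped fixtures and CI runs are reproducible.
DEFAULT_SEED = 20250410

_STUDY_TERMS = ("Studie", "Register", "Protokoll")
_INFO_TERMS = ("TACE", "Chemotherapie", "Erhaltungstherapie")

# dose/time decorations; every token they produce is removed by the default
# stoplist (bare numbers, number+unit fusions, unit and time literals)
_DOSE_DECOR = (
    "100mg", "250mg", "40mg", "500 mg", "2x täglich", "1x täglich",
    "5 Tage", "1 Zyklus",
)

_ONSETS = ("b", "c", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z")
_VOWELS = ("a", "e", "i", "o", "u")
_SUFFIXES = ("mab", "platin", "ukatin", "tinib", "rubicin", "taxel", "citabin", "zomib")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; all probabilities are per-entry (or per-token)."""

    seed: int = DEFAULT_SEED
    n_entries: int = 500
    regimen_fraction: float = 0.25
    study_fraction: float = 0.15
    info_fraction: float = 0.15
    dose_annotation_rate: float = 0.4
    typo_rate: float = 0.0
    n_substances: int = 50
    n_regimens: int = 8

    def __post_init__(self) -> None:
        for name in (
            "regimen_fraction", "study_fraction", "info_fraction",
            "dose_annotation_rate", "typo_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_entries", "n_substances", "n_regimens"):
            if getattr(self, name) < 0 or (name != "n_entries" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticCorpus:
    """Entries plus gold annotations and gold records, index-aligned."""

    entries: list[RawEntry] = field(default_factory=list)
    gold_annotations: list[GoldAnnotation] = field(default_factory=list)
    gold_records: list[StandardizedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def _invent_name(rng: random.Random, taken: set[str]) -> str:
    """A pronounceable invented substance name, unique among `taken`."""
    while True:
        n_syll = rng.randint(1, 3)
        stem = "".join(
            rng.choice(_ONSETS) + rng.choice(_VOWELS) for _ in range(n_syll)
        )
        name = (stem + rng.choice(_SUFFIXES)).capitalize()
        key = normalize_key(name)
        if key not in taken and len(key) >= 6:
            taken.add(key)
            return name


def _invent_code(rng: random.Random, first: str, taken: set[str]) -> str:
    while True:
        code = (
            first
            + f"{rng.randint(0, 99):02d}"
            + "".join(rng.choice("ABCDEFGHX") for _ in range(2))
            + f"{rng.randint(0, 99):02d}"
        )
        if code not in taken:
            taken.add(code)
            return code


def build_toy_atc(config: SyntheticConfig) -> AtcDictionary:
    """Invent ``n_substances`` names with valid level-5 codes (~70% chapter L).

    The first name always carries two codes — one antineoplastic, one not —
    so multi-code resolution is exercised by every fixture set.
    """
    rng = random.Random(config.seed)
    non_l = sorted(VALID_FIRST_LETTERS - {"L"})
    atc = AtcDictionary()
    names: set[str] = set()
    codes: set[str] = set()
    for i in range(config.n_substances):
        name = _invent_name(rng, names)
        first = "L" if rng.random() < 0.7 else rng.choice(non_l)
        atc.add(name, _invent_code(rng, first, codes), name=name)
        if i == 0:  # the Methotrexate-like situation: one 'L' code, one other
            atc.add(name, _invent_code(rng, "L", codes), name=name)
            atc.add(name, _invent_code(rng, rng.choice(non_l), codes), name=name)
    return atc


def build_toy_rad(atc: AtcDictionary, config: SyntheticConfig) -> RegimenDictionary:
    """Acronyms, abbreviations and routing terms over the toy ATC names."""
    rng = random.Random(config.seed + 1)
    rad = RegimenDictionary()
    names = sorted(atc.keys())
    taken = set(names)

    for _ in range(config.n_regimens):
        while True:
            acronym = "".join(rng.choice("ABCDEFGIKLMNOPRSTUVX") for _ in range(rng.randint(4, 7)))
            if acronym not in taken:
                taken.add(acronym)
                break
        members = tuple(rng.sample(names, rng.randint(2, 3)))
        rad.add(acronym, RadTarget(kind=RadKind.EXPANSION, names=members))

    # abbreviation keys: prefix truncations and hyphenated "5-<NAME>" aliases
    for name in rng.sample(names, min(6, len(names))):
        prefix = name[:5]
        if prefix not in taken:
            taken.add(prefix)
            rad.add(prefix, RadTarget(kind=RadKind.EXPANSION, names=(name,)))
    for name in rng.sample(names, min(4, len(names))):
        alias = f"5-{name}"  # normalizes to the hyphen-free key 5<NAME>
        if normalize_key(alias) not in taken:
            taken.add(normalize_key(alias))
            rad.add(alias, RadTarget(kind=RadKind.EXPANSION, names=(name,)))

    for term in _STUDY_TERMS:
        rad.add(term, RadTarget(kind=RadKind.STUDY, term=term))
    for term in _INFO_TERMS:
        rad.add(term, RadTarget(kind=RadKind.INFO, term=term))
    # a multi-token phrase routed to Info, and one recognized medication
    # name that has no ATC code
    rad.add("Best supportive care", RadTarget(kind=RadKind.INFO, term="best supportive care"))
    rad.add("Placebomycin", RadTarget(kind=RadKind.MEDICATION, term="Placebomycin"))
    return rad


def _resolved_code(atc: AtcDictionary, name_key: str) -> str:
    """Gold-side resolution: smallest 'L' code, else smallest code overall."""
    codes = sorted(atc.entries[name_key])
    l_codes = [c for c in codes if c.startswith("L")]
    return l_codes[0] if l_codes else codes[0]


def _transpose(
    rng: random.Random, token: str, known: frozenset[str], stoplist: Stoplist
) -> str | None:
    """One adjacent-letter transposition making the token unknown, or None."""
    positions = [i for i in range(len(token) - 1) if token[i] != token[i + 1]]
    rng.shuffle(positions)
    for i in positions:
        swapped = token[:i] + token[i + 1] + token[i] + token[i + 2:]
        if swapped not in known and not stoplist.matches(swapped):
            return swapped
    return None


def _render_case(rng: random.Random, name: str) -> str:
    return rng.choice((name, name.upper(), name.lower()))


def generate_entries(
    atc: AtcDictionary, rad: RegimenDictionary, config: SyntheticConfig
) -> SyntheticCorpus:
    """Generate free-text entries with gold labels from the generative choices.

    Each entry carries either one regimen acronym or 1–4 distinct substances
    (rendered with varied casing, occasionally through an abbreviation key
    or a "alias (Fullname)" parenthetical), plus optional dose, study and
    info decorations.  With probability ``typo_rate`` a written substance
    token (or the regimen acronym) is corrupted by one adjacent
    transposition; the gold annotation still expects its ATC code(s), which
    the pipeline must then fail to produce.
    """
    rng = random.Random(config.seed + 2)
    stoplist = default_stoplist()
    known = frozenset(atc.keys() | rad.keys())
    name_keys = sorted(atc.keys())
    display = {k: k.capitalize() for k in name_keys}
    regimens = sorted(
        k for k, t in rad.entries.items()
        if t.kind is RadKind.EXPANSION and len(t.names) > 1
    )
    # surface keys (abbreviations/aliases) per substance, for varied rendering
    aliases: dict[str, list[str]] = {}
    for key, target in rad.entries.items():
        if target.kind is RadKind.EXPANSION and len(target.names) == 1:
            aliases.setdefault(target.names[0], []).append(key)

    corpus = SyntheticCorpus()
    for i in range(config.n_entries):
        entry_id = f"E{i + 1:05d}"
        pieces: list[str] = []
        expected_tokens: list[tuple[str, str]] = []
        gold_anti: set[str] = set()
        gold_additional: set[str] = set()
        residuals: list[str] = []

        if regimens and rng.random() < config.regimen_fraction:
            acronym = rng.choice(regimens)
            members = rad.entries[acronym].names
            corrupt = rng.random() < config.typo_rate
            surface = acronym
            if corrupt:
                swapped = _transpose(rng, acronym, known, stoplist)
                if swapped is None:
                    corrupt = False
                else:
                    surface = swapped
            pieces.append(surface)
            for member in members:
                expected_tokens.append((member, _resolved_code(atc, member)))
            if corrupt:
                residuals.append(surface)
            else:
                for member in members:
                    code = _resolved_code(atc, member)
                    (gold_anti if code.startswith("L") else gold_additional).add(code)
        else:
            chosen = rng.sample(name_keys, rng.randint(1, 4))
            for name_key in chosen:
                code = _resolved_code(atc, name_key)
                expected_tokens.append((name_key, code))
                corrupt = rng.random() < config.typo_rate
                if corrupt:
                    swapped = _transpose(rng, name_key, known, stoplist)
                    if swapped is None:
                        corrupt = False
                    else:
                        pieces.append(_render_case(rng, swapped.capitalize()))
                        residuals.append(swapped)
                if not corrupt:
                    style = rng.random()
                    if style < 0.15 and aliases.get(name_key):
                        alias = rng.choice(aliases[name_key])
                        if rng.random() < 0.5:
                            # "5-FU (Fluorouracil)" style; RAD + dedup → one token
                            pieces.append(f"{alias} ({display[name_key]})")
                        else:
                            pieces.append(alias)
                    else:
                        pieces.append(_render_case(rng, display[name_key]))
                    (gold_anti if code.startswith("L") else gold_additional).add(code)

        gold_study: list[str] = []
        gold_info: list[str] = []
        if rng.random() < config.dose_annotation_rate:
            dose = rng.choice(_DOSE_DECOR)
            pieces.append(f"({dose})" if rng.random() < 0.3 else dose)
        if rng.random() < config.study_fraction:
            term = rng.choice(_STUDY_TERMS)
            gold_study.append(term)
            pieces.append(_render_case(rng, term))
        if rng.random() < config.info_fraction:
            term = rng.choice(_INFO_TERMS)
            gold_info.append(term)
            pieces.append(_render_case(rng, term))

        sep = rng.choice((" ", " + ", ", ", " / "))
        text = sep.join(pieces)
        if rng.random() < 0.1:
            text += "."

        corpus.entries.append(RawEntry(entry_id=entry_id, text=text))
        corpus.gold_annotations.append(
            GoldAnnotation(
                entry_id=entry_id,
                expected_tokens=tuple(expected_tokens),
                expected_study=tuple(gold_study),
                expected_info=tuple(gold_info),
            )
        )
        corpus.gold_records.append(
            StandardizedRecord(
                entry_id=entry_id,
                original_text=text,
                antineoplastic_medication=tuple(sorted(gold_anti)),
                additional_medication=tuple(sorted(gold_additional)),
                medication=(),
                study=tuple(gold_study),
                info=tuple(gold_info),
                residual_tokens=tuple(residuals),
            )
        )
    return corpus


def build_fixture_set(
    config: SyntheticConfig | None = None,
) -> tuple[AtcDictionary, RegimenDictionary, Stoplist, SyntheticCorpus]:
    """One-call construction of dictionaries, stoplist and corpus."""
    config = config or SyntheticConfig()
    atc = build_toy_atc(config)
    rad = build_toy_rad(atc, config)
    return atc, rad, default_stoplist(), generate_entries(atc, rad, config)


def write_fixture_dir(
    target: str | Path, config: SyntheticConfig | None = None
) -> dict[str, Path]:
    """Write atc.tsv, rad.tsv, stoplist.tsv, entries.csv and gold.tsv.

    File formats are identical to the production loaders; entries.csv is the
    single-column input table (header ``Medication_text``), rows in corpus
    order so entry ids E00001… are positional.
    """
    config = config or SyntheticConfig()
    atc, rad, stoplist, corpus = build_fixture_set(config)
    target = Path(target)
    target.mkdir(parents=True, exist_ok=True)
    paths = {
        "atc": target / "atc.tsv",
        "rad": target / "rad.tsv",
        "stoplist": target / "stoplist.tsv",
        "entries": target / "entries.csv",
        "gold": target / "gold.tsv",
    }
    atc.to_tsv(paths["atc"])
    rad.to_tsv(paths["rad"])
    stoplist.to_tsv(paths["stoplist"])
    lines = ["Medication_text"] + [_csv_quote(e.text) for e in corpus.entries]
    paths["entries"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    write_gold_tsv(corpus.gold_annotations, paths["gold"])
    return paths


def _csv_quote(value: str) -> str:
    if any(ch in value for ch in ',"\n'):
        return '"' + value.replace('"', '""') + '"'
    return value
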