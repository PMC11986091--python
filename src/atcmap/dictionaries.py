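"""Data model, loaders and validators for the two lookup dictionaries.

Two dictionaries drive the transformation:

* the **ATC dictionary** maps normalized surface patterns (substance names)
  to sets of level-5 ATC codes — a single name may carry several codes
  (Methotrexate is the canonical example);
* the **regimens-and-abbreviations dictionary (RAD)** maps regimen acronyms,
  abbreviations and routing terms to either a list of canonical substance
  names (EXPANSION) or a routing category (STUDY, INFO, MEDICATION).

Both are plain TSV files for diffability; a YAML nested-list dialect
mirroring the original quanteda-style structure is supported as an
alternative reader.  All keys and patterns are normalized with the same
rules applied to input text (transliterate → uppercase → hyphen-free), so a
dictionary hit is a pure string comparison at match time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .preprocess import normalize_key

__all__ = [
    "VALID_FIRST_LETTERS",
    "AtcCode",
    "validate_atc_code",
    "code_level",
    "level_prefixes",
    "AtcDictionary",
    "RadKind",
    "RadTarget",
    "RegimenDictionary",
    "match_pattern",
    "load_atc_dictionary",
    "load_rad",
    "load_atc_dictionary_yaml",
    "load_rad_yaml",
]

#: The 14 anatomical main groups of the ATC system (first code character).
VALID_FIRST_LETTERS: frozenset[str] = frozenset("ABCDGHJLMNPRSV")

# level → code length: main group 1 char, then 3, 4, 5, and the full
# 7-character level-5 code (letter, 2 digits, 2 letters, 2 digits).
_LEVEL_BY_LENGTH = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
_LEVEL_RES = {
    1: re.compile(r"^[A-Z]$"),
    2: re.compile(r"^[A-Z]\d{2}$"),
    3: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$"),
}


def validate_atc_code(code: str) -> tuple[bool, int | None]:
    """Check structural validity of an ATC code and report its level (1–5).

    A code is valid when its length corresponds to one of the five
    hierarchical levels, its character classes match that level's shape, and
    its first letter is one of the 14 anatomical groups.
    """
    level = _LEVEL_BY_LENGTH.get(len(code))
    if level is None:
        return False, None
    if not _LEVEL_RES[level].match(code):
        return False, None
    if code[0] not in VALID_FIRST_LETTERS:
        return False, None
    return True, level


def code_level(code: str) -> int | None:
    return validate_atc_code(code)[1]


def level_prefixes(code: str) -> set[str]:
    """The hierarchy prefixes of a full code, e.g. L01BA01 → {L, L01, L01B, L01BA, L01BA01}."""
    valid, level = validate_atc_code(code)
    if not valid or level != 5:
        raise ValueError(f"not a full level-5 ATC code: {code!r}")
    return {code[:n] for n in (1, 3, 4, 5, 7)}


@dataclass(frozen=True, order=True)
class AtcCode:
    """A WHO ATC classification code; full codes sit at level 5."""

    code: str

    @property
    def level(self) -> int | None:
        return code_level(self.code)

    @property
    def is_valid(self) -> bool:
        return validate_atc_code(self.code)[0]

    @property
    def is_antineoplastic(self) -> bool:
        return self.code.startswith("L")

    def __str__(self) -> str:
        return self.code


def match_pattern(token: str, pattern: str) -> bool:
    """Exact match by default; glob semantics when the pattern contains '*'.

    '*' matches zero or more of [A-Z0-9].  Both sides are expected to be
    normalized (uppercase, hyphen-free) already.
    """
    if "*" not in pattern:
        return token == pattern
    rx = "".join("[A-Z0-9]*" if ch == "*" else re.escape(ch) for ch in pattern)
    return re.fullmatch(rx, token) is not None


@dataclass
class AtcDictionary:
    """surface pattern → set of code strings, plus code → display name."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    name_of: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._glob_patterns = [p for p in self.entries if "*" in p]

    def add(self, pattern: str, code: str, name: str | None = None) -> None:
        pat = normalize_key(pattern)
        self.entries.setdefault(pat, set()).add(code)
        if "*" in pat and pat not in self._glob_patterns:
            self._glob_patterns.append(pat)
        if name and code not in self.name_of:
            self.name_of[code] = name

    def lookup(self, token: str) -> set[str]:
        """All candidate codes for a token (exact keys first, then globs)."""
        codes = set(self.entries.get(token, ()))
        for pat in self._glob_patterns:
            if match_pattern(token, pat):
                codes |= self.entries[pat]
        return codes

    def keys(self) -> frozenset[str]:
        """Literal (non-glob) keys, usable as stoplist protection."""
        return frozenset(p for p in self.entries if "*" not in p)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = ["# code\tname\tpattern"]
        for pat in sorted(self.entries):
            for code in sorted(self.entries[pat]):
                rows.append(f"{code}\t{self.name_of.get(code, '')}\t{pat}")
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


class RadKind(str, Enum):
    """What a RAD key stands for."""

    EXPANSION = "EXPANSION"  # regimen/abbreviation → substance names
    STUDY = "STUDY"          # clinical-trial indicator term
    INFO = "INFO"            # supplementary therapy information
    MEDICATION = "MEDICATION"  # recognized medication without an ATC code


@dataclass(frozen=True)
class RadTarget:
    kind: RadKind
    # EXPANSION: normalized substance names (≥1); routing kinds: display term
    names: tuple[str, ...] = ()
    term: str = ""


@dataclass
class RegimenDictionary:
    """Normalized key (single token or multi-token phrase) → RadTarget."""

    entries: dict[str, RadTarget] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, key: str, target: RadTarget) -> None:
        self.entries[normalize_key(key)] = target

    def get(self, key: str) -> RadTarget | None:
        return self.entries.get(key)

    def keys(self) -> frozenset[str]:
        return frozenset(self.entries)

    def single_token_keys(self) -> frozenset[str]:
        return frozenset(k for k in self.entries if " " not in k)

    def max_phrase_len(self) -> int:
        return max((k.count(" ") + 1 for k in self.entries), default=1)

    def __len__(self) -> int:
        return len(self.entries)

    def cross_check(self, atc: AtcDictionary) -> list[str]:
        """Warn about EXPANSION names that resolve to nothing in the ATC dictionary."""
        problems = []
        for key, target in self.entries.items():
            if target.kind is RadKind.EXPANSION:
                for name in target.names:
                    if not atc.lookup(name):
                        problems.append(
                            f"RAD key {key!r}: expansion name {name!r} not in ATC dictionary"
                        )
        return problems

    def to_tsv(self, path: str | Path) -> None:
        rows = ["# key\tkind\tpayload"]
        for key in sorted(self.entries):
            t = self.entries[key]
            payload = ";".join(t.names) if t.kind is RadKind.EXPANSION else t.term
            rows.append(f"{key}\t{t.kind.value}\t{payload}")
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def _read_tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = line.strip("\n")
        if not stripped.strip() or stripped.lstrip().startswith("#"):
            continue
        yield lineno, stripped.split("\t")


def load_atc_dictionary(path: str | Path, strict: bool = False) -> AtcDictionary:
    """Load an ATC dictionary TSV with columns code, name, pattern.

    The pattern column is optional per row and defaults to the normalized
    name.  Structurally invalid codes are kept with a warning (real-world
    registries contain pseudo-codes); with ``strict=True`` they raise.
    """
    d = AtcDictionary()
    for lineno, fields in _read_tsv_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: need at least columns code, name")
        code = fields[0].strip().upper()
        name = fields[1].strip()
        pattern = fields[2].strip() if len(fields) > 2 and fields[2].strip() else name
        if not code:
            raise ValueError(f"{path}:{lineno}: empty code")
        valid, _ = validate_atc_code(code)
        if not valid:
            msg = f"{path}:{lineno}: structurally invalid ATC code {code!r} (kept)"
            if strict:
                raise ValueError(msg)
            d.warnings.append(msg)
        d.add(pattern, code, name=name or None)
    return d


def load_rad(path: str | Path, atc: AtcDictionary | None = None) -> RegimenDictionary:
    """Load a RAD TSV with columns key, kind, payload.

    EXPANSION payloads are semicolon-separated substance names and are
    normalized like input text; routing kinds carry their display term
    verbatim.  If an ATC dictionary is given, expansions that resolve to no
    code are collected as warnings.
    """
    rad = RegimenDictionary()
    for lineno, fields in _read_tsv_rows(path):
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected columns key, kind, payload")
        key, kind_s, payload = (f.strip() for f in fields)
        try:
            kind = RadKind(kind_s.upper())
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unknown RAD kind {kind_s!r}") from None
        if kind is RadKind.EXPANSION:
            names = tuple(
                normalize_key(n) for n in payload.split(";") if n.strip()
            )
            if not names:
                raise ValueError(f"{path}:{lineno}: empty EXPANSION payload")
            rad.add(key, RadTarget(kind=kind, names=names))
        else:
            rad.add(key, RadTarget(kind=kind, term=payload or key))
    if atc is not None:
        rad.warnings.extend(rad.cross_check(atc))
    return rad


def load_atc_dictionary_yaml(path: str | Path, strict: bool = False) -> AtcDictionary:
    """Alternative reader: YAML mapping of code → list of surface patterns.

    Mirrors the nested-list dictionary structure of the original R tool::

        L01BA01: [Methotrexat, MTX]
    """
    data: Mapping[str, object] = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    d = AtcDictionary()
    for code, patterns in data.items():
        code = str(code).strip().upper()
        valid, _ = validate_atc_code(code)
        if not valid:
            msg = f"{path}: structurally invalid ATC code {code!r} (kept)"
            if strict:
                raise ValueError(msg)
            d.warnings.append(msg)
        if isinstance(patterns, str):
            patterns = [patterns]
        for i, pat in enumerate(patterns or []):
            d.add(str(pat), code, name=str(pat) if i == 0 else None)
    return d


def load_rad_yaml(path: str | Path) -> RegimenDictionary:
    """Alternative RAD reader: YAML mapping of target → list of surface keys.

    Top-level keys are either a routing category (STUDY, INFO, MEDICATION) or
    a semicolon-separated list of substance names (the expansion); values are
    the surface keys that map to it::

        Fluorouracil: [5-FU, 5FU]
        Fluorouracil;Calciumfolinat;Oxaliplatin: [FOLFOX]
        STUDY: [Studie, Register]
    """
    data: Mapping[str, object] = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    rad = RegimenDictionary()
    routing = {k.value for k in RadKind if k is not RadKind.EXPANSION}
    for target_s, keys in data.items():
        target_s = str(target_s).strip()
        if isinstance(keys, str):
            keys = [keys]
        for key in keys or []:
            key = str(key)
            if target_s.upper() in routing:
                rad.add(key, RadTarget(kind=RadKind(target_s.upper()), term=key))
            else:
                names = tuple(
                    normalize_key(n) for n in target_s.split(";") if n.strip()
                )
                if not names:
                    raise ValueError(f"{path}: empty expansion for key {key!r}")
                rad.add(key, RadTarget(kind=RadKind.EXPANSION, names=names))
    return rad
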