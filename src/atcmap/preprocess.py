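"""Text normalization, tokenization and noise filtering for medication free text.

German clinical medication entries mix substance names with dosages, routes,
time references and punctuation ("Cisplatin 100mg tägl.").  This module turns
each raw entry into a sequence of uppercase alphanumeric tokens:

1. umlaut/eszett transliteration (ä→ae, ö→oe, ü→ue, ß→ss, plus the uppercase
   forms Ä→AE, Ö→OE, Ü→UE, ẞ→SS),
2. tokenization on whitespace with punctuation and symbols acting as
   delimiters, while hyphens are deleted *in place* so that flanking parts
   fuse into a single token ("5-FU" → "5FU"),
3. uppercasing,
4. removal of noise tokens (units, time words, number/unit fusions) via a
   curated stoplist — except for tokens that are keys of a loaded dictionary,
   which are always kept.

All steps are deterministic and pure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RawEntry",
    "TokenSequence",
    "Stoplist",
    "DEFAULT_STOPLIST_LITERALS",
    "DEFAULT_STOPLIST_PATTERNS",
    "default_stoplist",
    "transliterate",
    "tokenize",
    "filter_tokens",
    "preprocess_entry",
    "normalize_key",
]

# Transliteration table.  The lowercase pairs are the classic German
# substitutions; uppercase forms are included because transliteration runs
# before uppercasing and clinical text contains capitalized words.
_TRANSLIT = str.maketrans(
    {
        "ä": "ae",
        "ö": "oe",
        "ü": "ue",
        "ß": "ss",
        "Ä": "AE",
        "Ö": "OE",
        "Ü": "UE",
        "ẞ": "SS",  # capital eszett
    }
)

# Hyphen-like characters are deleted without splitting the token.
_HYPHENS = re.compile(r"[-‐‑‒–—]")
# Everything that is not alphanumeric splits tokens (after hyphen removal).
_DELIMITERS = re.compile(r"[^0-9A-Za-z]+")

_TOKEN_RE = re.compile(r"^[A-Z0-9]+$")


@dataclass(frozen=True)
class RawEntry:
    """One free-text medication entry (one administration event)."""

    entry_id: str
    text: str


@dataclass(frozen=True)
class TokenSequence:
    """Ordered uppercase tokens derived from one entry."""

    entry_id: str
    tokens: tuple[str, ...]

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def transliterate(text: str) -> str:
    """Replace German umlauts and eszett by their ASCII digraphs.

    Idempotent; every other character is left untouched.
    """
    return text.translate(_TRANSLIT)


def tokenize(text: str, entry_id: str = "") -> TokenSequence:
    """Split transliterated text into uppercase alphanumeric tokens.

    Punctuation and symbols act as delimiters and are removed; hyphens are
    deleted without splitting, so ``5-FU`` becomes the single token ``5FU``.
    """
    dehyphenated = _HYPHENS.sub("", text)
    parts = _DELIMITERS.split(dehyphenated)
    tokens = tuple(p.upper() for p in parts if p)
    return TokenSequence(entry_id=entry_id, tokens=tokens)


def normalize_key(text: str) -> str:
    """Normalize a dictionary key or pattern exactly like input text.

    transliterate → hyphen fusion → delimiter split → uppercase; multi-word
    phrases keep a single space between words.  Glob stars survive
    normalization so patterned entries can be declared in dictionary files.
    """
    guard = "000GLOB000"  # alphanumeric so it survives tokenization
    seq = tokenize(transliterate(text).replace("*", guard))
    return " ".join(t.replace(guard, "*") for t in seq.tokens)


DEFAULT_STOPLIST_LITERALS: frozenset[str] = frozenset(
    {
        # measurement units
        "MG", "ML", "G", "IE",
        # time references
        "TAG", "TAGE", "WOCHE", "ZYKLUS", "TAEGLICH",
    }
)

# noise classes: bare numbers, number+short-unit fusions ("100MG", "2X")
DEFAULT_STOPLIST_PATTERNS: tuple[str, ...] = (r"^\d+$", r"^\d+[A-Z]{1,3}$")


@dataclass
class Stoplist:
    """Curated noise-token list: exact literals plus regex noise classes."""

    literals: frozenset[str] = field(default_factory=frozenset)
    patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self._compiled = [re.compile(p) for p in self.patterns]

    def matches(self, token: str) -> bool:
        if token in self.literals:
            return True
        return any(rx.search(token) for rx in self._compiled)

    def conflicts(self, protected: Iterable[str]) -> list[str]:
        """Dictionary keys that the stoplist would wrongly remove.

        Checked when a pipeline is assembled; conflicts are reported as
        warnings because dictionary membership always wins during filtering.
        """
        return sorted(k for k in set(protected) if self.matches(k))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Stoplist":
        """Read a stoplist TSV with columns ``kind`` (LITERAL|PATTERN), ``value``."""
        literals: set[str] = set()
        patterns: list[str] = []
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            kind, value = fields[0].strip().upper(), fields[1].strip()
            if kind == "LITERAL":
                literals.add(normalize_key(value))
            elif kind == "PATTERN":
                re.compile(value)  # fail fast on bad regex
                patterns.append(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown stoplist kind {kind!r}")
        return cls(literals=frozenset(literals), patterns=tuple(patterns))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# kind\tvalue"]
        lines += [f"LITERAL\t{lit}" for lit in sorted(self.literals)]
        lines += [f"PATTERN\t{pat}" for pat in self.patterns]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_stoplist() -> Stoplist:
    """The shipped starting stoplist (editable; see the stoplist TSV format)."""
    return Stoplist(
        literals=DEFAULT_STOPLIST_LITERALS, patterns=DEFAULT_STOPLIST_PATTERNS
    )


def filter_tokens(
    seq: TokenSequence,
    stoplist: Stoplist,
    protected: Sequence[str] | frozenset[str] = frozenset(),
) -> TokenSequence:
    """Drop stoplist noise tokens, keeping any token that is a dictionary key.

    `protected` is the union of RAD and ATC dictionary keys; protection takes
    precedence so that keys like ``5FU`` survive the number-prefix pattern.
    """
    protected_set = frozenset(protected)
    kept = tuple(
        t for t in seq.tokens if t in protected_set or not stoplist.matches(t)
    )
    return TokenSequence(entry_id=seq.entry_id, tokens=kept)


def preprocess_entry(
    entry: RawEntry,
    stoplist: Stoplist | None = None,
    protected: Sequence[str] | frozenset[str] = frozenset(),
) -> TokenSequence:
    """Full preprocessing of one raw entry: transliterate → tokenize → filter."""
    seq = tokenize(transliterate(entry.text), entry_id=entry.entry_id)
    if stoplist is None:
        return seq
    return filter_tokens(seq, stoplist, protected)
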