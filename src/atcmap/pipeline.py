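"""Two-stage transformation: RAD expansion, ATC lookup, resolution, assembly.

Each preprocessed token sequence is passed through:

1. **RAD stage** — regimen acronyms expand to their constituent substance
   names; study/info/medication terms are routed to side channels; the
   resulting sequence is deduplicated entry-wide (first occurrence kept),
   so "5-FU (Fluorouracil)" yields a single Fluorouracil token.
2. **ATC stage** — every token collects its full candidate code set from the
   ATC dictionary; unmatched tokens become residuals.
3. **Resolution** — a token with several candidate codes keeps the
   lexicographically smallest code starting with 'L' (antineoplastic
   priority); if none starts with 'L', the alphabetically first code wins.
   Resolution is per token (per substance), then codes are merged per entry.
4. **Assembly** — resolved codes are split by first letter into the
   AntineoplasticMedication ('L') and AdditionalMedication (non-'L')
   columns; routed terms fill Medication, Study and Info; residual tokens
   are retained in memory for evaluation but never exported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .dictionaries import AtcDictionary, RadKind, RegimenDictionary
from .preprocess import RawEntry, Stoplist, TokenSequence, preprocess_entry

logger = logging.getLogger(__name__)

__all__ = [
    "Routing",
    "TokenMatch",
    "RoutedTerms",
    "StandardizedRecord",
    "OUTPUT_COLUMNS",
    "rad_stage",
    "atc_stage",
    "resolve_multi_code",
    "assemble_record",
    "standardize_entry",
    "standardize",
    "records_to_frame",
]

#: The five derived output columns, in output order (after the echoed input).
OUTPUT_COLUMNS = (
    "AntineoplasticMedication",
    "AdditionalMedication",
    "Medication",
    "Study",
    "Info",
)


class Routing(str, Enum):
    ATC = "ATC"
    MEDICATION = "MEDICATION"
    STUDY = "STUDY"
    INFO = "INFO"
    RESIDUAL = "RESIDUAL"


@dataclass(frozen=True)
class TokenMatch:
    """One post-RAD token with its ATC candidates (empty set ⇒ residual)."""

    token: str
    candidate_codes: frozenset[str]
    routing: Routing


@dataclass
class RoutedTerms:
    """Side channels collected during the RAD stage."""

    medication: list[str] = field(default_factory=list)
    study: list[str] = field(default_factory=list)
    info: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class StandardizedRecord:
    """One output row: the verbatim input plus the five derived fields."""

    entry_id: str
    original_text: str
    antineoplastic_medication: tuple[str, ...]
    additional_medication: tuple[str, ...]
    medication: tuple[str, ...]
    study: tuple[str, ...]
    info: tuple[str, ...]
    residual_tokens: tuple[str, ...] = ()  # evaluation only, never exported

    def atc_codes(self) -> frozenset[str]:
        return frozenset(self.antineoplastic_medication) | frozenset(
            self.additional_medication
        )


def _dedup(tokens: Iterable[str]) -> tuple[str, ...]:
    """Entry-wide deduplication keeping first occurrence; idempotent."""
    seen: set[str] = set()
    out: list[str] = []
    for t in tokens:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return tuple(out)


def rad_stage(
    seq: TokenSequence, rad: RegimenDictionary
) -> tuple[TokenSequence, RoutedTerms]:
    """Expand regimens/abbreviations and route study/info/medication terms.

    Multi-token phrase keys are matched longest-first at each position before
    single-token lookup; unmatched tokens pass through unchanged.  The
    substituted sequence is deduplicated entry-wide.
    """
    routed = RoutedTerms()
    out: list[str] = []
    tokens = seq.tokens
    max_len = rad.max_phrase_len()
    i = 0
    while i < len(tokens):
        target = None
        span = 1
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            candidate = " ".join(tokens[i : i + n])
            target = rad.get(candidate)
            if target is not None:
                span = n
                break
        if target is None:
            out.append(tokens[i])
            i += 1
            continue
        if target.kind is RadKind.EXPANSION:
            out.extend(target.names)  # dictionary payload order
        elif target.kind is RadKind.STUDY:
            routed.study.append(target.term)
        elif target.kind is RadKind.INFO:
            routed.info.append(target.term)
        else:  # MEDICATION: recognized name without an ATC code
            routed.medication.append(target.term)
        i += span
    return TokenSequence(entry_id=seq.entry_id, tokens=_dedup(out)), routed


def atc_stage(seq: TokenSequence, atc: AtcDictionary) -> list[TokenMatch]:
    """Attach the full candidate code set to every post-RAD token."""
    matches = []
    for token in seq.tokens:
        codes = frozenset(atc.lookup(token))
        routing = Routing.ATC if codes else Routing.RESIDUAL
        matches.append(TokenMatch(token=token, candidate_codes=codes, routing=routing))
    return matches


def resolve_multi_code(codes: Iterable[str]) -> str:
    """Pick one code from a non-empty candidate set.

    Antineoplastic ('L') codes take priority; ties break alphabetically, and
    with no 'L' code at all the alphabetically first code is selected.
    """
    codes = sorted(codes)
    if not codes:
        raise ValueError("cannot resolve an empty code set")
    l_codes = [c for c in codes if c.startswith("L")]
    return l_codes[0] if l_codes else codes[0]


def assemble_record(
    entry: RawEntry, matches: Sequence[TokenMatch], routed: RoutedTerms
) -> StandardizedRecord:
    """Resolve per token, split codes by the 'L' prefix, and build the row."""
    anti: list[str] = []
    additional: list[str] = []
    residual: list[str] = []
    for m in matches:
        if m.routing is Routing.RESIDUAL:
            residual.append(m.token)
            continue
        code = resolve_multi_code(m.candidate_codes)
        (anti if code.startswith("L") else additional).append(code)
    return StandardizedRecord(
        entry_id=entry.entry_id,
        original_text=entry.text,
        antineoplastic_medication=tuple(sorted(set(anti))),
        additional_medication=tuple(sorted(set(additional))),
        medication=_dedup(routed.medication),
        study=_dedup(routed.study),
        info=_dedup(routed.info),
        residual_tokens=tuple(residual),
    )


def standardize_entry(
    entry: RawEntry,
    atc: AtcDictionary,
    rad: RegimenDictionary,
    stoplist: Stoplist | None = None,
) -> StandardizedRecord:
    """Run the full pipeline for a single entry."""
    protected = atc.keys() | rad.single_token_keys()
    seq = preprocess_entry(entry, stoplist=stoplist, protected=protected)
    post_rad, routed = rad_stage(seq, rad)
    matches = atc_stage(post_rad, atc)
    return assemble_record(entry, matches, routed)


def standardize(
    entries: Iterable[RawEntry],
    atc: AtcDictionary,
    rad: RegimenDictionary,
    stoplist: Stoplist | None = None,
) -> list[StandardizedRecord]:
    """Standardize a table of entries; one output record per input, same order.

    Content-level problems never abort the run: residual tokens are logged
    per entry (they feed the dictionary-refinement loop) and stoplist/
    dictionary conflicts are logged once up front.
    """
    protected = atc.keys() | rad.single_token_keys()
    if stoplist is not None:
        for key in stoplist.conflicts(protected):
            logger.warning(
                "stoplist would remove dictionary key %r; dictionary wins", key
            )
    records = []
    for entry in entries:
        seq = preprocess_entry(entry, stoplist=stoplist, protected=protected)
        post_rad, routed = rad_stage(seq, rad)
        record = assemble_record(entry, atc_stage(post_rad, atc), routed)
        if record.residual_tokens:
            logger.info(
                "entry %s: residual tokens %s",
                entry.entry_id,
                ", ".join(record.residual_tokens),
            )
        records.append(record)
    return records


def records_to_frame(
    records: Sequence[StandardizedRecord],
    input_column: str = "Medication_text",
    joiner: str = ", ",
) -> pd.DataFrame:
    """Serialize records to the six-column output frame.

    Empty cells are empty strings; multi-value cells are joined with
    ``joiner``.  Residual tokens are deliberately not exported.
    """
    rows = [
        {
            input_column: r.original_text,
            "AntineoplasticMedication": joiner.join(r.antineoplastic_medication),
            "AdditionalMedication": joiner.join(r.additional_medication),
            "Medication": joiner.join(r.medication),
            "Study": joiner.join(r.study),
            "Info": joiner.join(r.info),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=[input_column, *OUTPUT_COLUMNS])
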