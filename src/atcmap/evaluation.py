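"""Three-way evaluation taxonomy against gold annotations.

Given gold annotations (which tokens of each entry were expected to become
an ATC code, which names were expected as code-less medications, which
study/info terms should be extracted), every standardized entry is placed
in exactly one bucket:

* **successfully transformed** — every expected transformation is present;
* **error in transformation** — at least one expected transformation is
  missing from the output columns;
* **no useful information** — the entry produced no ATC code and no
  Medication/Study/Info content, and nothing was expected of it.

Rates are reported at the entry level and at the token level.  Only
"ATC code expected" tokens enter the token-level success/failure counts;
entries with no useful information count as one token each in the token
table.  The number of entries with extracted Study/Info content is reported
separately as the additional-information count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .dictionaries import validate_atc_code
from .pipeline import StandardizedRecord

__all__ = [
    "NAME_ONLY",
    "GoldAnnotation",
    "EntryBucket",
    "EntryOutcome",
    "EvaluationOutcome",
    "classify_entry",
    "summarize",
    "evaluate",
    "load_gold_tsv",
    "write_gold_tsv",
]

#: Sentinel in gold files for a token expected in the Medication column
#: (a recognized medication name without an ATC code).
NAME_ONLY = "NAME_ONLY"

_BUCKETS = ("successfully_transformed", "error_in_transformation", "no_useful_information")


@dataclass(frozen=True)
class GoldAnnotation:
    """Expected transformations for one entry.

    ``expected_tokens`` pairs each annotated token with either the ATC code
    it must produce or the ``NAME_ONLY`` sentinel (expected in the
    Medication column).  Study/info expectations carry the verbatim term.
    """

    entry_id: str
    expected_tokens: tuple[tuple[str, str], ...] = ()
    expected_study: tuple[str, ...] = ()
    expected_info: tuple[str, ...] = ()

    def expected_codes(self) -> tuple[tuple[str, str], ...]:
        return tuple((t, c) for t, c in self.expected_tokens if c != NAME_ONLY)

    def expects_anything(self) -> bool:
        return bool(self.expected_tokens or self.expected_study or self.expected_info)


class EntryBucket:
    SUCCESS = "successfully_transformed"
    ERROR = "error_in_transformation"
    NO_INFO = "no_useful_information"


@dataclass(frozen=True)
class EntryOutcome:
    """Classification of one entry plus its per-token tallies."""

    entry_id: str
    bucket: str
    n_expected_tokens: int  # "ATC code expected" tokens
    n_token_success: int
    n_token_failure: int
    failed_tokens: tuple[str, ...]
    has_additional_info: bool


@dataclass
class EvaluationOutcome:
    """Aggregated counts and rates, entry level and token level."""

    entry_counts: dict[str, int] = field(default_factory=dict)
    token_counts: dict[str, int] = field(default_factory=dict)
    n_entries: int = 0
    n_tokens: int = 0
    n_entries_with_additional_info: int = 0
    entry_rates: dict[str, float | None] = field(default_factory=dict)
    token_rates: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "entries": {"total": self.n_entries, **self.entry_counts,
                        "rates_percent": self.entry_rates},
            "tokens": {"total": self.n_tokens, **self.token_counts,
                       "rates_percent": self.token_rates},
            "entries_with_additional_info": self.n_entries_with_additional_info,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )

    def to_text(self) -> str:
        """Human-readable table mirroring the three-bucket report shape."""
        def fmt(n: int, rate: float | None) -> str:
            return f"{n} ({rate:.1f}%)" if rate is not None else f"{n} (—)"

        header = f"{'':14s}{'Overall':>14s}{'Success':>16s}{'Failed':>16s}{'No info':>16s}"
        erow = (
            f"{'Data entries':14s}{self.n_entries:>14d}"
            + "".join(
                f"{fmt(self.entry_counts[b], self.entry_rates[b]):>16s}" for b in _BUCKETS
            )
        )
        trow = (
            f"{'Tokens':14s}{self.n_tokens:>14d}"
            + "".join(
                f"{fmt(self.token_counts[b], self.token_rates[b]):>16s}" for b in _BUCKETS
            )
        )
        extra = f"Entries with additional information: {self.n_entries_with_additional_info}"
        return "\n".join([header, erow, trow, extra])


def classify_entry(record: StandardizedRecord, gold: GoldAnnotation) -> EntryOutcome:
    """Place one entry in its bucket and tally its expected tokens.

    A token expected to yield an ATC code succeeds iff that code appears in
    AntineoplasticMedication or AdditionalMedication; a NAME_ONLY token
    succeeds iff its name appears in the Medication column.  Any missing
    expectation (including study/info terms) makes the entry an error.
    """
    if record.entry_id != gold.entry_id:
        raise ValueError(
            f"entry_id mismatch: record {record.entry_id!r} vs gold {gold.entry_id!r}"
        )
    produced_codes = record.atc_codes()
    n_success = n_failure = 0
    failed: list[str] = []
    missing_other = False
    for token, expected in gold.expected_tokens:
        if expected == NAME_ONLY:
            if token not in record.medication:
                missing_other = True
            continue
        if expected in produced_codes:
            n_success += 1
        else:
            n_failure += 1
            failed.append(token)
    if any(term not in record.study for term in gold.expected_study):
        missing_other = True
    if any(term not in record.info for term in gold.expected_info):
        missing_other = True

    has_info = bool(record.study or record.info)
    produced_anything = bool(
        produced_codes or record.medication or record.study or record.info
    )
    if n_failure or missing_other:
        bucket = EntryBucket.ERROR
    elif not produced_anything and not gold.expects_anything():
        bucket = EntryBucket.NO_INFO
    else:
        bucket = EntryBucket.SUCCESS
    return EntryOutcome(
        entry_id=record.entry_id,
        bucket=bucket,
        n_expected_tokens=len(gold.expected_codes()),
        n_token_success=n_success,
        n_token_failure=n_failure,
        failed_tokens=tuple(failed),
        has_additional_info=has_info,
    )


def _pct(n: int, total: int) -> float | None:
    return round(100.0 * n / total, 1) if total else None


def summarize(outcomes: Sequence[EntryOutcome]) -> EvaluationOutcome:
    """Aggregate per-entry outcomes into the two-level report.

    Token totals are the "ATC code expected" tokens plus one token per
    no-useful-information entry; rates are percentages rounded to one
    decimal place, or null for an empty input.
    """
    entry_counts = {b: 0 for b in _BUCKETS}
    for o in outcomes:
        entry_counts[o.bucket] += 1
    n_entries = len(outcomes)

    tok_success = sum(o.n_token_success for o in outcomes)
    tok_failure = sum(o.n_token_failure for o in outcomes)
    tok_noinfo = entry_counts[EntryBucket.NO_INFO]
    token_counts = {
        EntryBucket.SUCCESS: tok_success,
        EntryBucket.ERROR: tok_failure,
        EntryBucket.NO_INFO: tok_noinfo,
    }
    n_tokens = tok_success + tok_failure + tok_noinfo
    return EvaluationOutcome(
        entry_counts=entry_counts,
        token_counts=token_counts,
        n_entries=n_entries,
        n_tokens=n_tokens,
        n_entries_with_additional_info=sum(o.has_additional_info for o in outcomes),
        entry_rates={b: _pct(entry_counts[b], n_entries) for b in _BUCKETS},
        token_rates={b: _pct(token_counts[b], n_tokens) for b in _BUCKETS},
    )


def evaluate(
    records: Sequence[StandardizedRecord],
    gold: Mapping[str, GoldAnnotation] | Iterable[GoldAnnotation],
) -> tuple[list[EntryOutcome], EvaluationOutcome]:
    """Classify every record against its gold annotation and aggregate.

    Records without gold (or gold without records) are a hard error listing
    the orphaned ids, since a silent partial evaluation would skew rates.
    """
    if not isinstance(gold, Mapping):
        gold = {g.entry_id: g for g in gold}
    record_ids = {r.entry_id for r in records}
    orphans = record_ids.symmetric_difference(gold.keys())
    if orphans:
        raise ValueError(
            "records and gold annotations do not match; orphaned ids: "
            + ", ".join(sorted(orphans))
        )
    outcomes = [classify_entry(r, gold[r.entry_id]) for r in records]
    return outcomes, summarize(outcomes)


def load_gold_tsv(path: str | Path) -> dict[str, GoldAnnotation]:
    """Read a gold TSV with columns entry_id, token, expected.

    ``expected`` is an ATC code, ``NAME_ONLY``, ``STUDY:<term>`` or
    ``INFO:<term>``.  An entry may span several rows; a row with an empty
    token and empty expected declares an entry expected to carry nothing.
    """
    rows: dict[str, dict] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not any(ln.strip() and not ln.lstrip().startswith("#") for ln in lines):
        raise ValueError(f"{path}: empty gold file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected columns entry_id, token, expected")
        entry_id, token, expected = (f.strip() for f in fields)
        slot = rows.setdefault(
            entry_id, {"tokens": [], "study": [], "info": []}
        )
        if not token and not expected:
            continue  # declares the entry with no expectations
        if expected.startswith("STUDY:"):
            slot["study"].append(expected[len("STUDY:"):])
        elif expected.startswith("INFO:"):
            slot["info"].append(expected[len("INFO:"):])
        elif expected == NAME_ONLY:
            slot["tokens"].append((token, NAME_ONLY))
        else:
            valid, _ = validate_atc_code(expected)
            if not valid:
                raise ValueError(
                    f"{path}:{lineno}: expected value {expected!r} is not a "
                    f"structurally valid ATC code, NAME_ONLY, STUDY:<term> or INFO:<term>"
                )
            slot["tokens"].append((token, expected))
    return {
        eid: GoldAnnotation(
            entry_id=eid,
            expected_tokens=tuple(slot["tokens"]),
            expected_study=tuple(slot["study"]),
            expected_info=tuple(slot["info"]),
        )
        for eid, slot in rows.items()
    }


def write_gold_tsv(gold: Iterable[GoldAnnotation], path: str | Path) -> None:
    rows = ["# entry_id\ttoken\texpected"]
    for g in gold:
        wrote = False
        for token, expected in g.expected_tokens:
            rows.append(f"{g.entry_id}\t{token}\t{expected}")
            wrote = True
        for term in g.expected_study:
            rows.append(f"{g.entry_id}\t\tSTUDY:{term}")
            wrote = True
        for term in g.expected_info:
            rows.append(f"{g.entry_id}\t\tINFO:{term}")
            wrote = True
        if not wrote:
            rows.append(f"{g.entry_id}\t\t")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
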