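"""Canonical data model and CSV I/O for the workflow master table.

The master table is the flat file at the heart of the analysis: one row per
(publication x species) axenisation attempt, carrying the ordered method
workflow, its outcome, the verification methods, antibiotic details and the
three raters' quality responses.  Species-level rows are the atomic records;
publication-level views are derived by grouping on ``publication_id``.

CSV dialect: UTF-8, comma-separated, all fields quoted on write.  The ordered
method list is serialised with ``;`` preserving application order; set-valued
fields (countries, verification methods, antibiotics) use ``|``.  Antibiotics
are serialised as ``compound:concentration`` tokens with concentration in
mg/L; the class is derived from the packaged compound lookup.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .quality import N_RATERS, RaterScores, RubricResponse
from .vocabulary import MethodDescriptor, classify_compound, method_vocabulary

DIVISIONS = ("diatoms", "dinoflagellates", "green_algae", "other")
OUTCOMES = ("success", "failure", "partial")
HABITATS = ("freshwater", "marine", "brackish", "unknown")

_RATER_COLUMNS = [f"r{i}_q{q}" for i in range(1, N_RATERS + 1) for q in range(1, 6)]
COLUMNS = [
    "publication_id",
    "year",
    "countries",
    "division",
    "species",
    "habitat",
    "media",
    "methods",
    "outcome",
    "verification_methods",
    "antibiotics",
    *_RATER_COLUMNS,
]


class SchemaError(ValueError):
    """The CSV header does not match the declared master-table schema."""


class ValidationError(ValueError):
    """A row violates a master-table invariant (named row and field)."""


class Antibiotic(NamedTuple):
    """One antibiotic application: class is derived from the compound."""

    a_class: str
    compound: str
    concentration: float  # mg/L


@dataclass(frozen=True)
class WorkflowRecord:
    """One publication x species axenisation attempt."""

    publication_id: str
    year: int
    countries: frozenset[str]
    division: str
    species: str
    habitat: str
    media: str
    methods: tuple[str, ...]
    outcome: str
    verification_methods: frozenset[str]
    antibiotics: tuple[Antibiotic, ...] = ()
    quality: RaterScores | None = None

    def __post_init__(self) -> None:
        if self.division not in DIVISIONS:
            raise ValidationError(f"unknown division {self.division!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"unknown habitat {self.habitat!r}")
        if not self.methods:
            raise ValidationError("workflow must contain at least one method")
        vocab = method_vocabulary()
        for code in self.methods:
            if code not in vocab:
                raise ValidationError(f"unknown method code {code!r}")
        for ab in self.antibiotics:
            if not ab.concentration > 0:
                raise ValidationError(
                    f"non-positive antibiotic concentration {ab.concentration!r} "
                    f"for {ab.compound!r}"
                )


@dataclass(frozen=True)
class MasterTable:
    """A validated collection of workflow records with provenance."""

    records: tuple[WorkflowRecord, ...]
    provenance: str = "<in-memory>"
    checksum: str | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.publication_id, rec.species)
            if key in seen:
                raise ValidationError(f"duplicate (publication, species) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def publication_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(r.publication_id for r in self.records))

    def to_dataframe(self) -> pd.DataFrame:
        """Flat view for ad-hoc analysis (list fields as serialised strings)."""
        return pd.DataFrame([_record_to_row(r) for r in self.records], columns=COLUMNS)


def _record_to_row(rec: WorkflowRecord) -> dict[str, str]:
    row = {
        "publication_id": rec.publication_id,
        "year": str(rec.year),
        "countries": "|".join(sorted(rec.countries)),
        "division": rec.division,
        "species": rec.species,
        "habitat": rec.habitat,
        "media": rec.media,
        "methods": ";".join(rec.methods),
        "outcome": rec.outcome,
        "verification_methods": "|".join(sorted(rec.verification_methods)),
        "antibiotics": "|".join(
            f"{ab.compound}:{ab.concentration:g}" for ab in rec.antibiotics
        ),
    }
    if rec.quality is None:
        raise ValidationError(
            f"record {rec.publication_id}/{rec.species} has no quality scores"
        )
    for i, resp in enumerate(rec.quality.responses, start=1):
        for q, answer in resp.answers().items():
            row[f"r{i}_{q}"] = answer
    return row


def _parse_row(
    row: Mapping[str, str], row_number: int, aliases: Mapping[str, str] | None
) -> WorkflowRecord:
    def fail(msg: str) -> ValidationError:
        return ValidationError(f"row {row_number}: {msg}")

    vocab = method_vocabulary()
    raw_methods = [m for m in row["methods"].split(";") if m]
    methods: list[str] = []
    for code in raw_methods:
        if code not in vocab and aliases and code in aliases:
            code = aliases[code]
        if code not in vocab:
            raise fail(f"unknown method code {code!r}")
        methods.append(code)
    if not methods:
        raise fail("empty method workflow")

    try:
        year = int(row["year"])
    except ValueError:
        raise fail(f"malformed year {row['year']!r}") from None

    antibiotics = []
    for token in filter(None, row["antibiotics"].split("|")):
        compound, _, conc = token.rpartition(":")
        try:
            concentration = float(conc)
        except ValueError:
            raise fail(f"malformed concentration in {token!r}") from None
        if not compound or concentration <= 0:
            raise fail(f"malformed antibiotic entry {token!r}")
        antibiotics.append(Antibiotic(classify_compound(compound), compound, concentration))

    try:
        responses = tuple(
            RubricResponse(*(row[f"r{i}_q{q}"] for q in range(1, 6)))
            for i in range(1, N_RATERS + 1)
        )
        return WorkflowRecord(
            publication_id=row["publication_id"],
            year=year,
            countries=frozenset(filter(None, row["countries"].split("|"))),
            division=row["division"],
            species=row["species"],
            habitat=row["habitat"],
            media=row["media"],
            methods=tuple(methods),
            outcome=row["outcome"],
            verification_methods=frozenset(
                filter(None, row["verification_methods"].split("|"))
            ),
            antibiotics=tuple(antibiotics),
            quality=RaterScores(responses),
        )
    except ValidationError:
        raise
    except ValueError as exc:
        raise fail(str(exc)) from None


def read_master_table(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> MasterTable:
    """Read and validate a master-table CSV.

    Parameters
    ----------
    path
        CSV file with the declared schema (see :data:`COLUMNS`).
    aliases
        Optional mapping from raw method labels to vocabulary codes, applied
        before validation; codes still unknown after aliasing are rejected
        with the offending row number.
    """
    path = Path(path)
    data = path.read_bytes()
    text = data.decode("utf-8")
    reader = csv.DictReader(io.StringIO(text))
    header = reader.fieldnames or []
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = [_parse_row(row, i, aliases) for i, row in enumerate(reader, start=2)]
    checksum = hashlib.sha256(data).hexdigest()
    return MasterTable(tuple(records), provenance=str(path), checksum=checksum)


def write_master_table(table: MasterTable, path: str | Path) -> None:
    """Write the table in canonical form: sorted rows, all fields quoted."""
    rows = sorted(
        (_record_to_row(r) for r in table.records),
        key=lambda r: (r["publication_id"], r["species"]),
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, quoting=csv.QUOTE_ALL)
        writer.writeheader()
        writer.writerows(rows)


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a raw-label -> method-code alias CSV (columns: raw_label, code)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or {"raw_label", "code"} - set(reader.fieldnames):
            raise SchemaError("alias table needs columns raw_label, code")
        return {row["raw_label"]: row["code"] for row in reader}


def filter_division(table: MasterTable, division: str) -> MasterTable:
    """Records of one division; the four division tables partition the table."""
    if division not in DIVISIONS:
        raise ValueError(f"unknown division {division!r} (choose from {DIVISIONS})")
    recs = tuple(r for r in table.records if r.division == division)
    return replace(table, records=recs, provenance=f"{table.provenance}[{division}]")


def concat_tables(tables: Iterable[MasterTable]) -> MasterTable:
    records: list[WorkflowRecord] = []
    for t in tables:
        records.extend(t.records)
    return MasterTable(tuple(records), provenance="<concat>")


def division_counts(table: MasterTable) -> dict[str, tuple[int, int]]:
    """Per division: (number of species-level records, number of publications)."""
    out: dict[str, tuple[int, int]] = {}
    for div in DIVISIONS:
        recs = [r for r in table.records if r.division == div]
        out[div] = (len(recs), len({r.publication_id for r in recs}))
    return out
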