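"""Per-method success rates with a representation filter, and division summaries.

The success rate of a method within a division is the number of
species-level records containing the method whose outcome was ``success``,
divided by the number of records containing it (each record counts once per
method regardless of repeats).  To avoid over-interpreting sparsely reported
methods, a rate is only defined when the method appears in *more than six*
records of the division; below that the entry is flagged below-filter-limit
(BFL).  Records with a ``partial`` outcome count toward uses but not toward
successes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .master_table import DIVISIONS, MasterTable
from .vocabulary import method_vocabulary

#: A method needs strictly more than this many species-level uses for a rate.
FILTER_LIMIT = 6


@dataclass(frozen=True)
class SuccessRateEntry:
    method: str
    division: str
    n_uses: int
    n_success: int

    @property
    def below_filter_limit(self) -> bool:
        return self.n_uses <= FILTER_LIMIT

    @property
    def rate(self) -> float | None:
        """Success fraction, or None when below the filter limit."""
        if self.below_filter_limit:
            return None
        return self.n_success / self.n_uses


def method_success_rates(table: MasterTable, division: str) -> list[SuccessRateEntry]:
    """One entry per method appearing in the division's records."""
    records = [r for r in table.records if r.division == division]
    if not records:
        raise ValueError(f"no records for division {division!r}")
    uses: Counter[str] = Counter()
    successes: Counter[str] = Counter()
    for rec in records:
        for code in set(rec.methods):  # once per record even if repeated
            uses[code] += 1
            if rec.outcome == "success":
                successes[code] += 1
    return [
        SuccessRateEntry(method=m, division=division, n_uses=uses[m], n_success=successes[m])
        for m in sorted(uses)
    ]


def success_rate_frame(entries: list[SuccessRateEntry]) -> pd.DataFrame:
    """Tabular view with rates to two decimals and a BFL marker."""
    return pd.DataFrame(
        {
            "division": e.division,
            "method": e.method,
            "n_uses": e.n_uses,
            "n_success": e.n_success,
            "rate": "BFL" if e.rate is None else f"{e.rate:.2f}",
        }
        for e in entries
    )


@dataclass(frozen=True)
class DivisionSummary:
    """Publication-level summary of one division (counts of major data points)."""

    division: str
    n_publications: int
    n_species: int
    method_type_counts: dict[str, int]  # unique methods per category
    n_genera: int
    media: dict[str, int]
    countries: dict[str, int]
    outcome_tally: dict[str, int]  # Yes / No / Multi/Part at publication level


def _publication_outcome(outcomes: set[str]) -> str:
    if outcomes == {"success"}:
        return "Yes"
    if outcomes == {"failure"}:
        return "No"
    return "Multi/Part"


def division_summary(table: MasterTable) -> dict[str, DivisionSummary]:
    """Per-division publication-level summary (empty divisions included)."""
    vocab = method_vocabulary()
    out: dict[str, DivisionSummary] = {}
    for div in DIVISIONS:
        records = [r for r in table.records if r.division == div]
        pubs: dict[str, set[str]] = {}
        methods: set[str] = set()
        media: Counter[str] = Counter()
        countries: Counter[str] = Counter()
        genera: set[str] = set()
        seen_media: set[tuple[str, str]] = set()
        for rec in records:
            pubs.setdefault(rec.publication_id, set()).add(rec.outcome)
            methods.update(rec.methods)
            genera.add(rec.species.split()[0] if rec.species else "")
            if (rec.publication_id, rec.media) not in seen_media and rec.media:
                seen_media.add((rec.publication_id, rec.media))
                media[rec.media] += 1
        for pub in pubs:
            for c in next(r for r in records if r.publication_id == pub).countries:
                countries[c] += 1
        tally = Counter(_publication_outcome(o) for o in pubs.values())
        out[div] = DivisionSummary(
            division=div,
            n_publications=len(pubs),
            n_species=len(records),
            method_type_counts={
                cat: sum(1 for m in methods if vocab[m].category == cat)
                for cat in ("Biological", "Chemical", "Physical")
            },
            n_genera=len(genera - {""}),
            media=dict(sorted(media.items())),
            countries=dict(sorted(countries.items())),
            outcome_tally={
                k: tally.get(k, 0) for k in ("Yes", "No", "Multi/Part")
            },
        )
    return out
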