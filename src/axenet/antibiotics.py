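"""Antibiotic class concentration summaries and cocktail co-occurrence.

Concentrations are summarised per (class x division) as median (min - max)
in mg/L over publication-level values: each publication contributes one
value per compound (the median of what it reported, e.g. across species
rows).  Cocktail analysis counts, for every unordered pair of compounds (or
classes), the number of publications reporting both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from statistics import median

import pandas as pd

from .master_table import DIVISIONS, MasterTable
from .vocabulary import ANTIBIOTIC_CLASSES, classify_compound


@dataclass(frozen=True)
class AntibioticUse:
    """One publication-level antibiotic application within a division."""

    publication_id: str
    division: str
    a_class: str
    compound: str
    concentration: float  # mg/L (publication-level value)


def collect_uses(table: MasterTable) -> list[AntibioticUse]:
    """Publication-level antibiotic uses: one entry per (publication, division,
    compound), concentration = median of the publication's reported values."""
    values: dict[tuple[str, str, str], list[float]] = {}
    for rec in table.records:
        for ab in rec.antibiotics:
            key = (rec.publication_id, rec.division, ab.compound)
            values.setdefault(key, []).append(ab.concentration)
    return [
        AntibioticUse(
            publication_id=pub,
            division=div,
            a_class=classify_compound(compound),
            compound=compound,
            concentration=float(median(conc)),
        )
        for (pub, div, compound), conc in sorted(values.items())
    ]


@dataclass(frozen=True)
class ConcentrationCell:
    median: float
    minimum: float
    maximum: float
    n: int

    def __str__(self) -> str:
        return f"{self.median:g} ({self.minimum:g}-{self.maximum:g})"


def class_concentration_summary(
    uses: list[AntibioticUse],
) -> dict[str, dict[str, ConcentrationCell]]:
    """Per antibiotic class x division: median (min-max) concentration.

    Cells with no reported use are absent (rendered as an em-dash in the
    tabular view).
    """
    grouped: dict[tuple[str, str], list[float]] = {}
    for u in uses:
        grouped.setdefault((u.a_class, u.division), []).append(u.concentration)
    out: dict[str, dict[str, ConcentrationCell]] = {}
    for (cls, div), values in grouped.items():
        out.setdefault(cls, {})[div] = ConcentrationCell(
            median=float(median(values)),
            minimum=min(values),
            maximum=max(values),
            n=len(values),
        )
    return out


def class_summary_frame(summary: dict[str, dict[str, ConcentrationCell]]) -> pd.DataFrame:
    """Class x division table mirroring the published layout."""
    rows = []
    for cls in ANTIBIOTIC_CLASSES:
        row: dict[str, str] = {"class": cls}
        for div in DIVISIONS:
            cell = summary.get(cls, {}).get(div)
            row[div] = str(cell) if cell else "-"
        if any(v != "-" for k, v in row.items() if k != "class"):
            rows.append(row)
    return pd.DataFrame(rows, columns=["class", *DIVISIONS])


def compound_frequency(uses: list[AntibioticUse]) -> pd.DataFrame:
    """Per compound: number of publications and median concentration (mg/L)."""
    pubs: dict[str, set[str]] = {}
    conc: dict[str, list[float]] = {}
    for u in uses:
        pubs.setdefault(u.compound, set()).add(u.publication_id)
        conc.setdefault(u.compound, []).append(u.concentration)
    rows = [
        {
            "compound": c,
            "class": classify_compound(c),
            "n_publications": len(pubs[c]),
            "median_concentration": float(median(conc[c])),
        }
        for c in sorted(pubs)
    ]
    frame = pd.DataFrame(rows, columns=["compound", "class", "n_publications", "median_concentration"])
    return frame.sort_values(
        ["n_publications", "compound"], ascending=[False, True], ignore_index=True
    )


def cocktail_combinations(
    uses: list[AntibioticUse],
) -> tuple[Counter[tuple[str, str]], Counter[tuple[str, str]]]:
    """Publication co-occurrence counts of compound pairs and class pairs.

    A publication with a single compound contributes no pairs; one with c
    compounds contributes C(c, 2) compound pairs.  Pairs are unordered and
    keyed by sorted tuple.
    """
    per_pub_compounds: dict[str, set[str]] = {}
    per_pub_classes: dict[str, set[str]] = {}
    for u in uses:
        per_pub_compounds.setdefault(u.publication_id, set()).add(u.compound)
        per_pub_classes.setdefault(u.publication_id, set()).add(u.a_class)
    compound_pairs: Counter[tuple[str, str]] = Counter()
    class_pairs: Counter[tuple[str, str]] = Counter()
    for compounds in per_pub_compounds.values():
        compound_pairs.update(combinations(sorted(compounds), 2))
    for classes in per_pub_classes.values():
        class_pairs.update(combinations(sorted(classes), 2))
    return compound_pairs, class_pairs


def n_publications_with_antibiotics(table: MasterTable) -> int:
    return len({r.publication_id for r in table.records if r.antibiotics})
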