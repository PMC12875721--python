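"""Controlled vocabularies: axenisation methods, verification methods, antibiotic classes.

The axenisation method vocabulary contains 24 four-letter codes grouped by
mode of action into three categories: Biological (methods leveraging
physiology of the alga, e.g. phototaxis), Chemical (compounds that kill or
inhibit contaminants, e.g. antibiotics or hypochlorite) and Physical (direct
manipulation, e.g. micropicking or filtration).  Flow cytometry (``FlCy``) is
counted among the Physical methods.  The terminal incubation step of every
workflow is represented by the reserved sink code ``INCB``, which is *not*
part of the 24-method vocabulary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

#: Reserved code for the terminal incubation sink node.
INCUBATION = "INCB"

CATEGORIES = ("Physical", "Chemical", "Biological")

VERIFICATION_GROUPS = ("microscopy", "counting", "sequencing", "physiology")

#: The twelve antibiotic classes used in the concentration summaries.
ANTIBIOTIC_CLASSES = (
    "Aminoglycosides",
    "Carbapenems",
    "Fluoroquinolones",
    "Penicillins",
    "Tetracyclines",
    "Cephalosporins",
    "Macrolides",
    "Polypeptides",
    "Rifamycins",
    "Nitrofurans",
    "Antifungal Agents",
    "Others",
)


@dataclass(frozen=True)
class MethodDescriptor:
    """One entry of the axenisation method vocabulary."""

    code: str
    name: str
    category: str

    def __post_init__(self) -> None:
        if len(self.code) != 4:
            raise ValueError(f"method code must be 4 characters: {self.code!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown method category: {self.category!r}")


@dataclass(frozen=True)
class VerificationDescriptor:
    """One verification (axenicity screening) method."""

    code: str
    name: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in VERIFICATION_GROUPS:
            raise ValueError(f"unknown verification group: {self.group!r}")


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("axenet.data").joinpath(name).read_text(encoding="utf-8")
    return list(csv.DictReader(text.splitlines()))


@lru_cache(maxsize=None)
def method_vocabulary() -> Mapping[str, MethodDescriptor]:
    """The 24-method vocabulary, keyed by code, in canonical (file) order."""
    rows = _read_packaged_csv("methods.csv")
    vocab = {r["code"]: MethodDescriptor(r["code"], r["name"], r["category"]) for r in rows}
    if len(vocab) != len(rows):
        raise ValueError("duplicate method codes in vocabulary resource")
    if INCUBATION in vocab:
        raise ValueError("the incubation sink code is reserved and cannot be a method")
    return vocab


@lru_cache(maxsize=None)
def verification_vocabulary() -> Mapping[str, VerificationDescriptor]:
    """Verification methods keyed by code.

    The figure legend of the source data distinguishes microscopy-, counting-,
    sequencing- and physiology-based checks; the packaged list carries that
    grouping.
    """
    rows = _read_packaged_csv("verification_methods.csv")
    return {r["code"]: VerificationDescriptor(r["code"], r["name"], r["group"]) for r in rows}


@lru_cache(maxsize=None)
def antibiotic_class_map() -> Mapping[str, str]:
    """Lookup from antibiotic compound (lower-case) to class.

    Compounds absent from the lookup belong to the catch-all ``Others`` class;
    use :func:`classify_compound` rather than indexing directly.
    """
    rows = _read_packaged_csv("antibiotic_classes.csv")
    mapping = {r["compound"].lower(): r["class"] for r in rows}
    unknown = set(mapping.values()) - set(ANTIBIOTIC_CLASSES)
    if unknown:
        raise ValueError(f"classes outside the closed vocabulary: {sorted(unknown)}")
    return mapping


def classify_compound(compound: str) -> str:
    """Map a compound name to its antibiotic class (``Others`` if unmapped)."""
    return antibiotic_class_map().get(compound.strip().lower(), "Others")
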