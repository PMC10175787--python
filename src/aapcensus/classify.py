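"""Localization, lipidation, tissue-expression, and COG classification.

Localization uses protein-level annotation: proteins carrying intramembrane,
topological-domain, or transmembrane annotations are integral membrane
proteins; proteins whose subcellular-location text names a peripheral
membrane association, or that carry a lipid anchor (farnesyl, myristoyl,
palmitoyl, geranylgeranyl), are peripheral membrane proteins; remaining
proteins located in the cytoplasm or cytoskeleton are cytoplasmic.  A
protein with both transmembrane and lipidation annotations is called
integral (the classes are disjoint, integral taking precedence).

Tissue expression rows are retained only with reliability enhanced,
supported, or approved (uncertain removed) and level high, medium, or low
(not-detected removed); tissue breadth is the number of distinct tissues
with a retained row, binned as 1, 2-5, 6-40, and >40 tissues.

COG functional categories are single letters; a multi-letter assignment
counts the protein once per category and once in the multi-category tally.
The letter -> broad-functional-group mapping (cellular processes and
signaling / information storage and processing / metabolism / poorly
characterized) ships as package data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError

__all__ = [
    "LocalizationCall",
    "CogAssignment",
    "LIPID_MODIFICATIONS",
    "EXPRESSION_LEVELS",
    "RELIABILITY_SCORES",
    "TISSUE_BINS",
    "classify_localization",
    "classify_localizations",
    "lipidation_summary",
    "filter_expression",
    "tissue_breadth",
    "cog_broad_groups",
    "summarize_cog",
]

LIPID_MODIFICATIONS = (
    "farnesylation",
    "myristoylation",
    "palmitoylation",
    "geranylgeranylation",
)

EXPRESSION_LEVELS = frozenset({"high", "medium", "low", "not_detected"})
RELIABILITY_SCORES = frozenset({"enhanced", "supported", "approved", "uncertain"})

#: Tissue-breadth histogram bins (number of distinct tissues with retained rows).
TISSUE_BINS = ("1", "2-5", "6-40", ">40")

_MEMBRANE_FLAGS = ("intramembrane", "topological_domain", "transmembrane")


@dataclass(frozen=True)
class LocalizationCall:
    protein: str
    cls: str  # integral_membrane | peripheral_membrane | cytoplasmic | other
    lipid_mods: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CogAssignment:
    protein: str
    categories: frozenset[str]
    broad_groups: frozenset[str]


def _truthy(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def _lipid_mods(row: Mapping) -> frozenset[str]:
    text = str(row.get("lipidation", "") or "").lower()
    return frozenset(m for m in LIPID_MODIFICATIONS if m in text)


def classify_localization(row: Mapping) -> LocalizationCall:
    """Classify one protein metadata row into a single localization class.

    Pure function of the row; missing fields default to the ``other`` class.
    """
    protein = str(row.get("accession", ""))
    mods = _lipid_mods(row)
    location = str(row.get("subcellular_location", "") or "").lower()
    if any(_truthy(row.get(flag)) for flag in _MEMBRANE_FLAGS):
        cls = "integral_membrane"
    elif "peripheral membrane" in location or mods:
        cls = "peripheral_membrane"
    elif "cytoplasm" in location or "cytoskeleton" in location:
        cls = "cytoplasmic"
    else:
        cls = "other"
    return LocalizationCall(protein=protein, cls=cls, lipid_mods=mods)


def classify_localizations(metadata: pd.DataFrame) -> list[LocalizationCall]:
    return [classify_localization(row) for row in metadata.to_dict("records")]


def lipidation_summary(calls: Iterable[LocalizationCall]) -> dict[str, int]:
    """Tally lipid modifications: per-type counts plus the multi-modified count.

    A protein with two modification types counts once per type and once under
    ``multiple``; ``any`` counts proteins with at least one modification.
    """
    counts = {m: 0 for m in LIPID_MODIFICATIONS}
    counts["any"] = 0
    counts["multiple"] = 0
    for call in calls:
        if not call.lipid_mods:
            continue
        counts["any"] += 1
        for m in call.lipid_mods:
            counts[m] += 1
        if len(call.lipid_mods) > 1:
            counts["multiple"] += 1
    return counts


def filter_expression(records: pd.DataFrame) -> pd.DataFrame:
    """Keep expression rows with trusted reliability and detected expression.

    Retains exactly rows with reliability != uncertain and level !=
    not_detected.  Idempotent.  Unknown vocabulary tokens are format errors.
    """
    bad_rel = set(records["reliability"].astype(str)) - RELIABILITY_SCORES
    if bad_rel:
        raise FormatError(f"unknown reliability value(s): {sorted(bad_rel)}")
    bad_level = set(records["level"].astype(str)) - EXPRESSION_LEVELS
    if bad_level:
        raise FormatError(f"unknown expression level(s): {sorted(bad_level)}")
    mask = (records["reliability"] != "uncertain") & (records["level"] != "not_detected")
    return records[mask].reset_index(drop=True)


def _bin_breadth(n: int) -> str:
    if n <= 1:
        return "1"
    if n <= 5:
        return "2-5"
    if n <= 40:
        return "6-40"
    return ">40"


def tissue_breadth(filtered: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Per-protein distinct-tissue counts and the breadth histogram.

    The histogram bins (1, 2-5, 6-40, >40) partition every protein with at
    least one retained expression row.
    """
    counts = (
        filtered.groupby("protein")["tissue"].nunique().sort_index()
        if len(filtered)
        else pd.Series(dtype=int, name="tissue")
    )
    hist = {b: 0 for b in TISSUE_BINS}
    for n in counts:
        hist[_bin_breadth(int(n))] += 1
    return counts, hist


def cog_broad_groups() -> dict[str, str]:
    """COG category letter -> broad functional group, from packaged data."""
    with resources.files("aapcensus.data").joinpath("cog_categories.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["letter"], df["broad_group"]))


def summarize_cog(
    cog_table: pd.DataFrame, census_proteins: Iterable[str] | None = None
) -> tuple[list[CogAssignment], dict]:
    """Split multi-letter COG strings into categories and aggregate.

    Returns the per-protein assignments (restricted to ``census_proteins``
    when given) and a summary: single- vs multi-category protein counts,
    per-category counts, and per-broad-group protein totals (a protein with
    categories in two groups counts once in each).
    """
    groups = cog_broad_groups()
    keep = None if census_proteins is None else set(census_proteins)
    assignments: list[CogAssignment] = []
    for row in cog_table.to_dict("records"):
        protein = str(row["protein"])
        if keep is not None and protein not in keep:
            continue
        letters = [c for c in str(row["categories"]).strip() if not c.isspace()]
        unknown = [c for c in letters if c not in groups]
        if unknown:
            raise FormatError(f"unknown COG category letter(s) {unknown} for {protein}")
        cats = frozenset(letters)
        if not cats:
            continue
        assignments.append(
            CogAssignment(
                protein=protein,
                categories=cats,
                broad_groups=frozenset(groups[c] for c in cats),
            )
        )
    per_category: dict[str, int] = {}
    per_group: dict[str, int] = {}
    n_single = n_multi = 0
    for a in assignments:
        if len(a.categories) == 1:
            n_single += 1
        else:
            n_multi += 1
        for c in sorted(a.categories):
            per_category[c] = per_category.get(c, 0) + 1
        for g in sorted(a.broad_groups):
            per_group[g] = per_group.get(g, 0) + 1
    summary = {
        "n_assigned": len(assignments),
        "n_single_category": n_single,
        "n_multi_category": n_multi,
        "per_category": dict(sorted(per_category.items())),
        "per_broad_group": dict(sorted(per_group.items())),
    }
    return assignments, summary
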