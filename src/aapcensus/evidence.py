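"""Evidence harvesting and census assembly for actin-associated proteins (AAPs).

Three lines of evidence identify a protein as actin-associated:

1. **Interaction evidence** — the protein is a physical interaction partner of
   one of the actin query proteins in a source interaction database, with a
   confidence score strictly above that database's threshold (each database
   scores on its own native scale).
2. **Domain evidence** — the protein's accepted domain architecture contains
   at least one family from a curated list of actin-binding domains (ABDs).
3. **Annotation evidence** — the protein carries an actin-related GO term,
   either directly in its protein-level annotation, through the GO terms
   mapped to its accepted domain families (pfam2go), or through a curated
   structure-derived list; plus a manually curated literature list.

The census is the union of all evidence streams, one entry per canonical
accession (splice-isoform suffixes collapsed), with full provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domains import DomainArchitecture
from .errors import ConfigurationError, FormatError, UsageError

__all__ = [
    "PPIEdge",
    "DatabaseThreshold",
    "EvidenceRecord",
    "CensusEntry",
    "DEFAULT_THRESHOLDS",
    "INTERACTION_TYPES",
    "canonical_accession",
    "read_edge_file",
    "read_edge_dir",
    "ppi_evidence",
    "domain_evidence",
    "go_evidence",
    "read_pfam2go",
    "read_accession_list",
    "build_census",
    "census_to_frame",
    "write_census",
]

INTERACTION_TYPES = frozenset({"physical", "functional", "unspecified"})

_ISOFORM_RE = re.compile(r"-\d+$")


def canonical_accession(accession: str) -> str:
    """Strip a splice-isoform suffix ("-N") to obtain the canonical accession."""
    return _ISOFORM_RE.sub("", accession)


@dataclass(frozen=True)
class PPIEdge:
    """A scored interaction between two proteins from one source database."""

    a: str
    b: str
    database: str
    score: float
    interaction_type: str = "unspecified"
    score2: float | None = None  # secondary score (e.g. method-based confidence)


@dataclass(frozen=True)
class DatabaseThreshold:
    """Acceptance rule for one interaction database.

    ``score_min is None`` means the source ships only high-confidence
    interactions and no score filter is applied.  Thresholds are strict:
    an edge passes only with ``score > score_min`` (and ``score2 > score2_min``
    where a secondary score threshold is configured).
    """

    score_min: float | None
    scale_max: float = 1.0
    requires_physical: bool = True
    score2_min: float | None = None

    def passes(self, edge: PPIEdge) -> bool:
        if self.requires_physical and edge.interaction_type != "physical":
            return False
        if self.score_min is not None and not edge.score > self.score_min:
            return False
        if self.score2_min is not None:
            if edge.score2 is None or not edge.score2 > self.score2_min:
                return False
        return True


#: Per-database confidence thresholds, each on the database's native scale.
DEFAULT_THRESHOLDS: dict[str, DatabaseThreshold] = {
    "string": DatabaseThreshold(score_min=700, scale_max=1000),
    "biogrid": DatabaseThreshold(score_min=0.6),
    "dip": DatabaseThreshold(score_min=None),
    "hint": DatabaseThreshold(score_min=None),
    "huri": DatabaseThreshold(score_min=None),
    "intact": DatabaseThreshold(score_min=0.6),
    "mint": DatabaseThreshold(score_min=0.6),
    "mentha": DatabaseThreshold(score_min=0.6),
    "hitpredict": DatabaseThreshold(score_min=0.5, score2_min=0.485),
    "hippie": DatabaseThreshold(score_min=0.73),
}

EVIDENCE_SOURCES = frozenset(
    {"pfam_domain", "go:uniprot", "go:pfam2go", "go:pdb", "literature"}
    | {f"ppi:{db}" for db in DEFAULT_THRESHOLDS}
)


@dataclass(frozen=True)
class EvidenceRecord:
    """One (protein, source) assertion of actin association.

    ``detail`` carries the witness: the actin partner for interaction
    evidence, the matched domain family, or the GO term.
    """

    protein: str
    source: str
    detail: str = ""
    score: float | None = None


@dataclass
class CensusEntry:
    """A canonical protein with the union of its evidence."""

    protein: str
    sources: frozenset[str]
    records: tuple[EvidenceRecord, ...]
    architecture: DomainArchitecture | None = None


def read_edge_file(path: str | Path, database: str | None = None) -> list[PPIEdge]:
    """Read one per-database edge TSV: columns a, b, score, interaction_type[, score2].

    The database name defaults to the file stem.
    """
    path = Path(path)
    database = database or path.stem
    df = pd.read_csv(path, sep="\t", dtype={"a": str, "b": str})
    required = {"a", "b", "score", "interaction_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    edges = []
    for row in df.to_dict("records"):
        itype = str(row["interaction_type"])
        if itype not in INTERACTION_TYPES:
            raise FormatError(
                f"{path.name}: unknown interaction_type {itype!r} "
                f"(expected one of {sorted(INTERACTION_TYPES)})"
            )
        score2 = row.get("score2")
        if score2 is not None and pd.isna(score2):
            score2 = None
        edges.append(
            PPIEdge(
                a=str(row["a"]),
                b=str(row["b"]),
                database=database,
                score=float(row["score"]),
                interaction_type=itype,
                score2=None if score2 is None else float(score2),
            )
        )
    return edges


def read_edge_dir(directory: str | Path) -> dict[str, list[PPIEdge]]:
    """Read every ``*.tsv`` edge file in a directory, keyed by file stem."""
    directory = Path(directory)
    return {
        p.stem: read_edge_file(p) for p in sorted(directory.glob("*.tsv"))
    }


def ppi_evidence(
    edges_by_db: Mapping[str, Sequence[PPIEdge]],
    actin_set: Iterable[str],
    thresholds: Mapping[str, DatabaseThreshold] | None = None,
    include_actins: bool = False,
) -> list[EvidenceRecord]:
    """Harvest interaction evidence: partners of the actin query set.

    For each edge touching an actin accession, the non-actin endpoint yields
    a record iff the edge passes the database's threshold rule (physical
    interaction where required; score strictly above the minimum, both scores
    for dual-threshold databases; no filter where none is configured).  Actin
    query accessions themselves are excluded from the partner set unless
    ``include_actins`` is set.
    """
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    actins = set(actin_set)
    records: list[EvidenceRecord] = []
    for db in sorted(edges_by_db):
        if db not in thresholds:
            raise ConfigurationError(f"no threshold configured for database {db!r}")
        rule = thresholds[db]
        for edge in edges_by_db[db]:
            if not (0 <= edge.score <= rule.scale_max):
                raise FormatError(
                    f"{db}: score {edge.score} outside scale [0, {rule.scale_max}]"
                )
            touching = {edge.a, edge.b} & actins
            if not touching:
                continue
            for endpoint, partner in ((edge.a, edge.b), (edge.b, edge.a)):
                if endpoint not in actins:
                    continue
                if partner in actins and not include_actins:
                    continue
                if partner == endpoint:
                    continue
                if rule.passes(edge):
                    records.append(
                        EvidenceRecord(
                            protein=canonical_accession(partner),
                            source=f"ppi:{db}",
                            detail=endpoint,
                            score=edge.score,
                        )
                    )
    return records


def domain_evidence(
    architectures: Mapping[str, DomainArchitecture], abd_families: Iterable[str]
) -> list[EvidenceRecord]:
    """One record per protein whose accepted architecture contains an ABD family."""
    abd = set(abd_families)
    if not abd:
        raise ConfigurationError("abd_families must not be empty")
    records = []
    for protein in sorted(architectures):
        matched = [f for f in architectures[protein].families if f in abd]
        if matched:
            records.append(
                EvidenceRecord(
                    protein=canonical_accession(protein),
                    source="pfam_domain",
                    detail=",".join(dict.fromkeys(matched)),
                )
            )
    return records


def read_pfam2go(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column family -> GO-term mapping (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def go_evidence(
    source_tag: str,
    go_term_list: Iterable[str],
    metadata: pd.DataFrame | None = None,
    pfam2go: Mapping[str, set[str]] | None = None,
    architectures: Mapping[str, DomainArchitecture] | None = None,
    curated_list: Iterable[str] | None = None,
) -> list[EvidenceRecord]:
    """Harvest GO-annotation evidence under one of three source tags.

    - ``go:uniprot`` — the protein's own GO annotation (``go_terms`` column of
      the metadata table, semicolon-separated) intersects the actin term list.
    - ``go:pfam2go`` — an accepted domain family of the protein maps, via the
      family->GO mapping, to a term in the list.
    - ``go:pdb`` — the protein appears in a supplied curated list.
    """
    terms = set(go_term_list)
    if not terms:
        raise ConfigurationError("go_term_list must not be empty")
    records: list[EvidenceRecord] = []
    if source_tag == "go:uniprot":
        if metadata is None:
            raise UsageError("go:uniprot evidence requires the protein metadata table")
        for row in metadata.to_dict("records"):
            annotated = {t for t in str(row.get("go_terms", "")).split(";") if t}
            hit = sorted(annotated & terms)
            if hit:
                records.append(
                    EvidenceRecord(
                        protein=canonical_accession(str(row["accession"])),
                        source=source_tag,
                        detail=",".join(hit),
                    )
                )
    elif source_tag == "go:pfam2go":
        if pfam2go is None or architectures is None:
            raise UsageError("go:pfam2go evidence requires pfam2go map and architectures")
        for protein in sorted(architectures):
            hit_terms: list[str] = []
            for fam in architectures[protein].families:
                hit_terms.extend(sorted(pfam2go.get(fam, set()) & terms))
            if hit_terms:
                records.append(
                    EvidenceRecord(
                        protein=canonical_accession(protein),
                        source=source_tag,
                        detail=",".join(dict.fromkeys(hit_terms)),
                    )
                )
    elif source_tag == "go:pdb":
        if curated_list is None:
            raise UsageError("go:pdb evidence requires a curated accession list")
        for acc in sorted(set(curated_list)):
            records.append(
                EvidenceRecord(
                    protein=canonical_accession(acc), source=source_tag, detail=acc
                )
            )
    else:
        raise UsageError(f"unknown GO evidence source tag {source_tag!r}")
    # one record per canonical protein per source
    seen: dict[str, EvidenceRecord] = {}
    for rec in records:
        seen.setdefault(rec.protein, rec)
    return list(seen.values())


def read_accession_list(path: str | Path) -> list[str]:
    """Read a one-entry-per-line curated list (accessions, families, or GO IDs)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def build_census(
    record_streams: Iterable[Iterable[EvidenceRecord]],
    literature_list: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> list[CensusEntry]:
    """Merge evidence streams into one provenance-tracked entry per canonical protein.

    Isoform accessions are collapsed to their canonical accession; the
    literature list is added as its own evidence source; accessions in
    ``exclude`` (typically the actin query set) are dropped.
    """
    excluded = {canonical_accession(a) for a in exclude}
    by_protein: dict[str, list[EvidenceRecord]] = {}
    for stream in record_streams:
        for rec in stream:
            acc = canonical_accession(rec.protein)
            if acc in excluded:
                continue
            by_protein.setdefault(acc, []).append(rec)
    for acc in sorted(set(literature_list)):
        acc = canonical_accession(acc)
        if acc in excluded:
            continue
        by_protein.setdefault(acc, []).append(
            EvidenceRecord(protein=acc, source="literature", detail="curated")
        )
    entries = []
    for protein in sorted(by_protein):
        records = tuple(by_protein[protein])
        entries.append(
            CensusEntry(
                protein=protein,
                sources=frozenset(r.source for r in records),
                records=records,
            )
        )
    return entries


def census_to_frame(entries: Sequence[CensusEntry]) -> pd.DataFrame:
    rows = [
        {
            "protein": e.protein,
            "sources": ";".join(sorted(e.sources)),
            "n_sources": len(e.sources),
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=["protein", "sources", "n_sources"])


def write_census(
    entries: Sequence[CensusEntry], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    census_to_frame(entries).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            e.protein: {
                "sources": sorted(e.sources),
                "records": [
                    {
                        "source": r.source,
                        "detail": r.detail,
                        "score": r.score,
                    }
                    for r in e.records
                ],
            }
            for e in entries
        }
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))
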