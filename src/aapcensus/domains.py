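"""Domain-architecture assignment from profile-HMM scan hits.

A protein's domain architecture is the ordered list of domain-family hits
that survive significance and model-coverage filtering and a greedy overlap
resolution.  Filtering keeps hits with an independent (per-domain) E-value
at or below a cutoff and a model coverage — the fraction of the HMM spanned
by the hit's model coordinates — at or above a cutoff.  Overlap resolution
then walks candidates in order of increasing independent E-value and accepts
a hit only if it overlaps every already-accepted hit by at most a fixed
residue tolerance, so that when several families align to the same region
the most significant one wins.

Defaults follow common practice for architecture building on Pfam-style
scans: independent E-value <= 1e-3, model coverage >= 0.7, pairwise overlaps
of up to 25 residues tolerated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, UsageError

__all__ = [
    "DomainHit",
    "FilterConfig",
    "DomainArchitecture",
    "parse_hits",
    "filter_hits",
    "resolve_architecture",
    "resolve_architectures",
    "assign_clans",
    "read_clan_map",
    "architectures_to_frame",
    "write_architectures",
    "HIT_COLUMNS",
]

#: Column order of the native tab-separated hit dialect.
HIT_COLUMNS = (
    "protein",
    "family",
    "clan",
    "ali_from",
    "ali_to",
    "hmm_from",
    "hmm_to",
    "model_length",
    "full_sequence_evalue",
    "independent_evalue",
    "bit_score",
)


@dataclass(frozen=True)
class DomainHit:
    """One domain-family match on one protein.

    Coordinates are 1-based inclusive: ``ali_from``/``ali_to`` on the protein
    sequence (alignment, not envelope, coordinates) and ``hmm_from``/``hmm_to``
    on the family model of length ``model_length``.
    """

    protein: str
    family: str
    clan: str | None
    ali_from: int
    ali_to: int
    hmm_from: int
    hmm_to: int
    model_length: int
    full_sequence_evalue: float
    independent_evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (1 <= self.ali_from <= self.ali_to):
            raise FormatError(
                f"invalid alignment coordinates {self.ali_from}..{self.ali_to} "
                f"for {self.protein}/{self.family}"
            )
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise FormatError(
                f"invalid model coordinates {self.hmm_from}..{self.hmm_to} "
                f"(model length {self.model_length}) for {self.protein}/{self.family}"
            )
        if self.independent_evalue <= 0 or self.full_sequence_evalue <= 0:
            raise FormatError(
                f"E-values must be positive for {self.protein}/{self.family}"
            )

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1

    @property
    def model_coverage(self) -> float:
        return (self.hmm_to - self.hmm_from + 1) / self.model_length


@dataclass(frozen=True)
class FilterConfig:
    """Post-scan filter and overlap-resolution parameters.

    ``scan_evalue_max`` documents the upstream scan-stage sequence E-value;
    it is a property of how the hit table was produced and is not re-applied
    here.
    """

    scan_evalue_max: float = 0.01
    independent_evalue_max: float = 0.001
    model_coverage_min: float = 0.7
    overlap_tolerance: int = 25

    def __post_init__(self) -> None:
        for name in ("scan_evalue_max", "independent_evalue_max"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.model_coverage_min <= 1):
            raise ConfigurationError("model_coverage_min must be in (0, 1]")
        if self.overlap_tolerance < 0:
            raise ConfigurationError("overlap_tolerance must be non-negative")


@dataclass(frozen=True)
class DomainArchitecture:
    """Overlap-resolved, position-ordered accepted domains of one protein."""

    protein: str
    domains: tuple[DomainHit, ...] = field(default_factory=tuple)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(d.family for d in self.domains)

    @property
    def architecture_string(self) -> str:
        return "~".join(self.families)


def _hit_from_row(row: Mapping, index: int) -> DomainHit:
    try:
        clan = row.get("clan")
        if clan is None or (isinstance(clan, float) and pd.isna(clan)) or clan in ("", "-", "None"):
            clan = None
        return DomainHit(
            protein=str(row["protein"]),
            family=str(row["family"]),
            clan=clan,
            ali_from=int(row["ali_from"]),
            ali_to=int(row["ali_to"]),
            hmm_from=int(row["hmm_from"]),
            hmm_to=int(row["hmm_to"]),
            model_length=int(row["model_length"]),
            full_sequence_evalue=float(row["full_sequence_evalue"]),
            independent_evalue=float(row["independent_evalue"]),
            bit_score=float(row["bit_score"]),
        )
    except FormatError as exc:
        raise FormatError(f"row {index}: {exc}") from exc
    except (ValueError, TypeError) as exc:
        raise FormatError(f"row {index}: malformed value ({exc})") from exc


# fixed column positions of HMMER3 per-domain tabular output (--domtblout)
_DOMTBL_NCOL = 22


def _parse_domtblout(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(maxsplit=_DOMTBL_NCOL)
            if len(parts) < _DOMTBL_NCOL:
                raise FormatError(
                    f"line {lineno}: expected >= {_DOMTBL_NCOL} columns, got {len(parts)}"
                )
            family = parts[1] if parts[1] != "-" else parts[0]
            row = {
                "protein": parts[3],
                "family": family,
                "clan": None,
                "model_length": parts[2],
                "full_sequence_evalue": parts[6],
                "independent_evalue": parts[12],
                "bit_score": parts[13],
                "hmm_from": parts[15],
                "hmm_to": parts[16],
                "ali_from": parts[17],
                "ali_to": parts[18],
            }
            hits.append(_hit_from_row(row, lineno))
    return hits


def parse_hits(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Read a domain-hit table into validated :class:`DomainHit` records.

    Parameters
    ----------
    path
        Hit table file.
    dialect
        ``"tsv"`` for the native tab-separated dialect (columns
        :data:`HIT_COLUMNS`), or ``"domtblout"`` for the standard 22+-column
        space-delimited per-domain tabular output of HMMER-style scanners,
        mapped by column position.

    Raises
    ------
    FormatError
        Missing column, non-numeric field, or coordinate-invariant violation,
        reported with the offending row number.
    """
    path = Path(path)
    if dialect == "domtblout":
        return _parse_domtblout(path)
    if dialect != "tsv":
        raise UsageError(f"unknown hit-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    return [_hit_from_row(row, i) for i, row in enumerate(df.to_dict("records"), start=1)]


def filter_hits(hits: Sequence[DomainHit], config: FilterConfig | None = None) -> list[DomainHit]:
    """Keep hits passing the independent E-value and model-coverage filters.

    Retains exactly the hits with ``independent_evalue <= independent_evalue_max``
    and ``model_coverage >= model_coverage_min``; input order is preserved.
    """
    config = config or FilterConfig()
    return [
        h
        for h in hits
        if h.independent_evalue <= config.independent_evalue_max
        and h.model_coverage >= config.model_coverage_min
    ]


def overlap(a: DomainHit, b: DomainHit) -> int:
    """Residue overlap of two hits on the protein: max(0, min(to) - max(from) + 1)."""
    return max(0, min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1)


def _priority(h: DomainHit) -> tuple:
    # ascending E-value; ties: longer alignment, then left-most, then family name
    return (h.independent_evalue, -h.ali_length, h.ali_from, h.family)


def resolve_architecture(
    hits: Sequence[DomainHit], config: FilterConfig | None = None
) -> DomainArchitecture:
    """Greedily resolve overlapping hits of one protein into an architecture.

    Candidates are visited in ascending independent E-value; a candidate is
    accepted iff its overlap with every already-accepted domain is at most
    ``overlap_tolerance`` residues.  When several families align to the same
    region the lowest-E-value one therefore wins.  Ties on E-value are broken
    deterministically (longer alignment, smaller start, family name).

    The accepted set is maximal: every rejected hit conflicts with some
    accepted hit of lower-or-equal E-value.
    """
    config = config or FilterConfig()
    proteins = {h.protein for h in hits}
    if len(proteins) > 1:
        raise UsageError(f"hits span multiple proteins: {sorted(proteins)}")
    if not hits:
        raise UsageError("cannot resolve an architecture from zero hits")
    accepted: list[DomainHit] = []
    for cand in sorted(hits, key=_priority):
        if all(overlap(cand, a) <= config.overlap_tolerance for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda h: (h.ali_from, h.ali_to))
    return DomainArchitecture(protein=proteins.pop(), domains=tuple(accepted))


def resolve_architectures(
    hits: Iterable[DomainHit], config: FilterConfig | None = None
) -> dict[str, DomainArchitecture]:
    """Filter and resolve a mixed-protein hit list; one architecture per protein."""
    config = config or FilterConfig()
    by_protein: dict[str, list[DomainHit]] = {}
    for h in filter_hits(list(hits), config):
        by_protein.setdefault(h.protein, []).append(h)
    return {
        p: resolve_architecture(hs, config) for p, hs in sorted(by_protein.items())
    }


def read_clan_map(path: str | Path) -> dict[str, str]:
    """Load a two-column family -> clan TSV.

    A family listed twice with conflicting clans is a format error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            family, clan = parts
            if family in mapping and mapping[family] != clan:
                raise FormatError(
                    f"line {lineno}: family {family} mapped to both "
                    f"{mapping[family]} and {clan}"
                )
            mapping[family] = clan
    return mapping


def assign_clans(
    architectures: Mapping[str, DomainArchitecture], clan_map: Mapping[str, str]
) -> dict[str, DomainArchitecture]:
    """Populate the clan field of each accepted domain from a family->clan map.

    Families absent from the map keep ``clan = None``; that is not an error.
    """
    out: dict[str, DomainArchitecture] = {}
    for protein, arch in architectures.items():
        domains = tuple(
            replace(d, clan=clan_map.get(d.family)) for d in arch.domains
        )
        out[protein] = DomainArchitecture(protein=protein, domains=domains)
    return out


def architectures_to_frame(architectures: Mapping[str, DomainArchitecture]) -> pd.DataFrame:
    rows = []
    for protein in sorted(architectures):
        arch = architectures[protein]
        rows.append(
            {
                "protein": protein,
                "n_domains": len(arch.domains),
                "architecture": arch.architecture_string,
                "families": ";".join(arch.families),
                "clans": ";".join(d.clan or "-" for d in arch.domains),
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "n_domains", "architecture", "families", "clans"]
    )


def write_architectures(
    architectures: Mapping[str, DomainArchitecture], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write per-protein architectures as TSV and, optionally, full JSON."""
    architectures_to_frame(architectures).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            p: [dataclasses.asdict(d) for d in architectures[p].domains]
            for p in sorted(architectures)
        }
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))
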