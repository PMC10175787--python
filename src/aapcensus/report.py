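"""Pipeline orchestration and catalog-style summary tables.

Runs the full census workflow — (optional) fixture generation, domain
architecture assignment, evidence harvesting, census assembly,
localization/tissue/COG classification, and term enrichment — and writes
TSV/JSON outputs plus a recountable summary.  All summary figures are
direct recounts of the underlying tables, so any of them can be verified
independently from the written files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import classify as _classify
from . import domains as _domains
from . import enrich as _enrich
from . import evidence as _evidence
from .errors import ConfigurationError
from .fixtures import SimulationConfig, simulate_all

__all__ = ["PipelineConfig", "CensusSummary", "summarize_census", "run_pipeline"]

logger = logging.getLogger("aapcensus")


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    With ``simulate`` set, fixtures are generated under
    ``output_dir/fixtures`` and all input paths are derived from them;
    otherwise every input path must be supplied and exist.
    """

    output_dir: Path
    simulate: SimulationConfig | None = None
    metadata: Path | None = None
    hits: Path | None = None
    hits_dialect: str = "tsv"
    edges_dir: Path | None = None
    expression: Path | None = None
    cog: Path | None = None
    clan_map: Path | None = None
    pfam2go: Path | None = None
    actins: Path | None = None
    abd_families: Path | None = None
    go_terms: Path | None = None
    pdb_curated: Path | None = None
    literature: Path | None = None
    filter_config: _domains.FilterConfig = field(default_factory=_domains.FilterConfig)
    thresholds: Mapping[str, _evidence.DatabaseThreshold] = field(
        default_factory=lambda: dict(_evidence.DEFAULT_THRESHOLDS)
    )
    report_fdr_max: float = _enrich.DEFAULT_FDR_MAX
    include_actins: bool = False
    force: bool = False

    _INPUT_FIELDS = (
        "metadata",
        "hits",
        "edges_dir",
        "expression",
        "cog",
        "clan_map",
        "pfam2go",
        "actins",
        "abd_families",
        "go_terms",
        "pdb_curated",
        "literature",
    )

    def validate(self) -> None:
        if self.simulate is None:
            missing = [f for f in self._INPUT_FIELDS if getattr(self, f) is None]
            if missing:
                raise ConfigurationError(
                    f"no fixture simulation requested and input path(s) missing: {missing}"
                )
            absent = [
                f for f in self._INPUT_FIELDS if not Path(getattr(self, f)).exists()
            ]
            if absent:
                raise ConfigurationError(f"input path(s) do not exist: {absent}")
            for p in sorted(Path(self.edges_dir).glob("*.tsv")):
                if p.stem not in self.thresholds:
                    raise ConfigurationError(
                        f"edge file {p.name} has no configured threshold"
                    )


@dataclass
class CensusSummary:
    """Recountable headline figures of one census run."""

    n_proteins: int
    per_source_counts: dict[str, int]
    per_actin_partner_counts: dict[str, int]
    n_distinct_families: int
    n_distinct_clans: int
    n_distinct_architectures: int
    top_families: list[tuple[str, int]]
    top_clans: list[tuple[str, int]]
    localization_breakdown: dict[str, int]
    lipidation: dict[str, int]
    tissue_histogram: dict[str, int]
    cog: dict
    n_enriched_terms: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_census(
    entries: list[_evidence.CensusEntry],
    architectures: Mapping[str, _domains.DomainArchitecture] | None = None,
    calls: list[_classify.LocalizationCall] | None = None,
    cog_summary: dict | None = None,
    tissue_histogram: dict[str, int] | None = None,
    n_enriched_terms: int = 0,
    top_n: int = 20,
) -> CensusSummary:
    """Aggregate a census into its headline figures.

    Family/clan/architecture counts are over the census proteins' accepted
    architectures (isoform architectures counted via their canonical
    accession); top tables are sorted by count descending then name.
    """
    census_set = {e.protein for e in entries}
    per_source: dict[str, int] = {}
    per_actin: dict[str, int] = {}
    for e in entries:
        for s in sorted(e.sources):
            per_source[s] = per_source.get(s, 0) + 1
        actins_hit = {r.detail for r in e.records if r.source.startswith("ppi:")}
        for a in sorted(actins_hit):
            per_actin[a] = per_actin.get(a, 0) + 1

    fam_counts: dict[str, int] = {}
    clan_counts: dict[str, int] = {}
    arch_strings: set[str] = set()
    if architectures:
        for protein in sorted(architectures):
            if _evidence.canonical_accession(protein) not in census_set:
                continue
            arch = architectures[protein]
            arch_strings.add(arch.architecture_string)
            for fam in set(arch.families):
                fam_counts[fam] = fam_counts.get(fam, 0) + 1
            for clan in {d.clan for d in arch.domains if d.clan}:
                clan_counts[clan] = clan_counts.get(clan, 0) + 1

    def top(counts: dict[str, int]) -> list[tuple[str, int]]:
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]

    loc_breakdown: dict[str, int] = {}
    lipid: dict[str, int] = {m: 0 for m in _classify.LIPID_MODIFICATIONS}
    if calls is not None:
        for c in calls:
            loc_breakdown[c.cls] = loc_breakdown.get(c.cls, 0) + 1
        lipid = _classify.lipidation_summary(calls)

    return CensusSummary(
        n_proteins=len(entries),
        per_source_counts=dict(sorted(per_source.items())),
        per_actin_partner_counts=dict(sorted(per_actin.items())),
        n_distinct_families=len(fam_counts),
        n_distinct_clans=len(clan_counts),
        n_distinct_architectures=len(arch_strings),
        top_families=top(fam_counts),
        top_clans=top(clan_counts),
        localization_breakdown=dict(sorted(loc_breakdown.items())),
        lipidation=lipid,
        tissue_histogram=tissue_histogram or {},
        cog=cog_summary or {},
        n_enriched_terms=n_enriched_terms,
    )


def _stage(name: str):
    logger.info("stage %s ...", name)
    return time.perf_counter()


def _done(name: str, t0: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %s done in %.2fs (%s)", name, time.perf_counter() - t0, extra)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write all outputs under ``output_dir``.

    Returns a dict with the census entries, architectures, summary, and
    output paths.  Refuses to overwrite an existing census unless
    ``config.force`` is set; a missing threshold or input path aborts before
    any stage runs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    census_tsv = outdir / "census.tsv"
    if census_tsv.exists() and not config.force:
        raise ConfigurationError(
            f"{census_tsv} already exists; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        t0 = _stage("simulate")
        paths = simulate_all(config.simulate, outdir / "fixtures", force=config.force)
        config.metadata = paths["metadata"]
        config.hits = paths["domain_hits"]
        config.edges_dir = paths["metadata"].parent / "edges"
        config.expression = paths["expression"]
        config.cog = paths["cog"]
        config.clan_map = paths["clan_map"]
        config.pfam2go = paths["pfam2go"]
        config.actins = paths["actins"]
        config.abd_families = paths["abd_families"]
        config.go_terms = paths["actin_go_terms"]
        config.pdb_curated = paths["pdb_curated"]
        config.literature = paths["literature"]
        _done("simulate", t0, files=len(paths))

    # --- load shared inputs -------------------------------------------------
    metadata = pd.read_csv(config.metadata, sep="\t", dtype={"accession": str})
    actin_set = _evidence.read_accession_list(config.actins)
    abd_families = _evidence.read_accession_list(config.abd_families)
    go_terms = _evidence.read_accession_list(config.go_terms)
    pdb_curated = _evidence.read_accession_list(config.pdb_curated)
    literature = _evidence.read_accession_list(config.literature)
    pfam2go = _evidence.read_pfam2go(config.pfam2go)
    clan_map = _domains.read_clan_map(config.clan_map)

    # --- domain architectures -----------------------------------------------
    t0 = _stage("domains")
    hits = _domains.parse_hits(config.hits, dialect=config.hits_dialect)
    architectures = _domains.resolve_architectures(hits, config.filter_config)
    architectures = _domains.assign_clans(architectures, clan_map)
    _domains.write_architectures(
        architectures, outdir / "architectures.tsv", outdir / "architectures.json"
    )
    _done("domains", t0, hits=len(hits), proteins=len(architectures))

    # --- evidence and census ------------------------------------------------
    t0 = _stage("evidence")
    edges = _evidence.read_edge_dir(config.edges_dir)
    streams = [
        _evidence.ppi_evidence(
            edges, actin_set, config.thresholds, include_actins=config.include_actins
        ),
        _evidence.domain_evidence(architectures, abd_families),
        _evidence.go_evidence("go:uniprot", go_terms, metadata=metadata),
        _evidence.go_evidence(
            "go:pfam2go", go_terms, pfam2go=pfam2go, architectures=architectures
        ),
        _evidence.go_evidence("go:pdb", go_terms, curated_list=pdb_curated),
    ]
    entries = _evidence.build_census(
        streams,
        literature_list=literature,
        exclude=() if config.include_actins else actin_set,
    )
    _evidence.write_census(entries, census_tsv, outdir / "census.json")
    _done("evidence", t0, records=sum(len(s) for s in streams), census=len(entries))

    census_set = {e.protein for e in entries}

    # --- classification -----------------------------------------------------
    t0 = _stage("classify")
    census_meta = metadata[metadata["accession"].isin(census_set)]
    calls = _classify.classify_localizations(census_meta)
    loc_frame = pd.DataFrame(
        [
            {
                "protein": c.protein,
                "class": c.cls,
                "lipid_mods": ";".join(sorted(c.lipid_mods)),
            }
            for c in calls
        ],
        columns=["protein", "class", "lipid_mods"],
    ).sort_values("protein", kind="stable")
    loc_frame.to_csv(outdir / "localization.tsv", sep="\t", index=False)

    expression = pd.read_csv(config.expression, sep="\t", dtype=str)
    expression = expression[expression["protein"].isin(census_set)]
    retained = _classify.filter_expression(expression)
    breadth, hist = _classify.tissue_breadth(retained)
    breadth.rename("n_tissues").to_frame().reset_index().to_csv(
        outdir / "tissue_breadth.tsv", sep="\t", index=False
    )

    cog_table = pd.read_csv(config.cog, sep="\t", dtype=str)
    cog_assignments, cog_summary = _classify.summarize_cog(cog_table, census_set)
    pd.DataFrame(
        [
            {
                "protein": a.protein,
                "categories": "".join(sorted(a.categories)),
                "broad_groups": ";".join(sorted(a.broad_groups)),
            }
            for a in cog_assignments
        ],
        columns=["protein", "categories", "broad_groups"],
    ).to_csv(outdir / "cog_assignments.tsv", sep="\t", index=False)
    _done("classify", t0, calls=len(calls), expression_rows=len(retained))

    # --- enrichment ---------------------------------------------------------
    t0 = _stage("enrich")
    background = sorted(
        {_evidence.canonical_accession(a) for a in metadata["accession"]}
    )
    term_map: dict[str, set[str]] = {}
    for row in metadata.to_dict("records"):
        acc = _evidence.canonical_accession(str(row["accession"]))
        for term in str(row.get("go_terms", "")).split(";"):
            if term:
                term_map.setdefault(term, set()).add(acc)
    study = sorted(census_set & set(background))
    results = _enrich.enrich_terms(study, background, term_map)
    _enrich.results_to_frame(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    n_enriched = sum(r.fdr <= config.report_fdr_max for r in results)
    _done("enrich", t0, terms=len(results), enriched=n_enriched)

    # --- summary ------------------------------------------------------------
    summary = summarize_census(
        entries,
        architectures=architectures,
        calls=calls,
        cog_summary=cog_summary,
        tissue_histogram=hist,
        n_enriched_terms=n_enriched,
    )
    (outdir / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1, sort_keys=True)
    )

    return {
        "entries": entries,
        "architectures": architectures,
        "calls": calls,
        "tissue_histogram": hist,
        "cog_summary": cog_summary,
        "enrichment": results,
        "summary": summary,
        "output_dir": outdir,
    }
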