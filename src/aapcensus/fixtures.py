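"""Synthetic inputs with planted ground truth for the whole census pipeline.

The generator emulates every input format the pipeline consumes — protein
FASTA and metadata, an HMM-scan-style domain-hit table, per-database
interaction edge lists, a tissue-expression table, an ortholog/COG table,
and the curated reference lists — with a planted set of true
actin-associated proteins (AAPs) and a per-protein plan of which evidence
sources should discover each of them.

Planting is adversarial on both sides of every filter: planted features
qualify strictly (scores above threshold, hits passing significance and
coverage, physical interaction type), while dedicated decoy proteins carry
features that fail exactly one rule each (sub-threshold scores, functional
interactions, hits above the E-value cutoff or below the coverage cutoff,
hits evicted by overlap resolution).  Recovering exactly the planted set is
therefore a sharp end-to-end test of the published-threshold rules.

Sequences are random residues: no downstream stage reads residue identities,
only lengths and identifiers.  Identical configuration (including seed)
yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError
from .evidence import DEFAULT_THRESHOLDS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticProteome",
    "simulate_proteome",
    "simulate_domain_hits",
    "simulate_ppi_edges",
    "simulate_expression",
    "simulate_cog",
    "simulate_all",
    "ABD_FAMILIES",
    "ACTIN_GO_TERMS",
    "PFAM2GO",
    "CLAN_MAP",
]

# --- reference vocabularies planted into the synthetic universe ------------

#: Curated actin-binding domain families (evidence line: domain architecture).
ABD_FAMILIES = ("CH", "VHP", "Gelsolin")

#: Actin-related GO terms used for annotation mining.
ACTIN_GO_TERMS = ("GO:0003779", "GO:0015629", "GO:0051015")

#: Family -> GO mapping; WH2 and Cofilin_ADF link to actin terms, PH does not.
PFAM2GO: dict[str, tuple[str, ...]] = {
    "WH2": ("GO:0003779",),
    "Cofilin_ADF": ("GO:0015629",),
    "PH": ("GO:0005515",),
    "Pkinase": ("GO:0004672",),
}
_PFAM2GO_ACTIN = ("WH2", "Cofilin_ADF")

NEUTRAL_GO_TERMS = (
    "GO:0005515",
    "GO:0016020",
    "GO:0005634",
    "GO:0005739",
    "GO:0003677",
    "GO:0005524",
)

NEUTRAL_FAMILIES = ("Pkinase", "PH", "SH3_1", "LIM", "RRM_1", "PDZ", "Ank_2")

MODEL_LENGTHS: dict[str, int] = {
    "CH": 110,
    "VHP": 35,
    "Gelsolin": 90,
    "WH2": 18,
    "Cofilin_ADF": 130,
    "Pkinase": 260,
    "PH": 105,
    "SH3_1": 60,
    "LIM": 55,
    "RRM_1": 70,
    "PDZ": 85,
    "Ank_2": 60,
}

#: Family -> clan map; LIM, VHP and WH2 deliberately have no clan.
CLAN_MAP: dict[str, str] = {
    "CH": "CL0188",
    "Gelsolin": "CL0092",
    "Cofilin_ADF": "CL0092",
    "Pkinase": "CL0016",
    "PH": "CL0266",
    "SH3_1": "CL0010",
    "RRM_1": "CL0221",
    "PDZ": "CL0466",
    "Ank_2": "CL0465",
}

COG_LETTERS = "JAKLBDYVTMNZWUOXCGEFHIPQRS"

_AA = "ACDEFGHIKLMNPQRSTVWY"

_MIX_TO_SOURCE = {
    "pfam_domain": "pfam_domain",
    "go_uniprot": "go:uniprot",
    "go_pfam2go": "go:pfam2go",
    "go_pdb": "go:pdb",
    "literature": "literature",
}


def _default_mix() -> dict[str, float]:
    return {
        "ppi": 0.70,
        "pfam_domain": 0.30,
        "go_uniprot": 0.30,
        "go_pfam2go": 0.15,
        "go_pdb": 0.05,
        "literature": 0.10,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic universe.

    Defaults: 500 proteins including 6 actin queries and 120 planted AAPs
    with mixed evidence, 50 tissues (so every breadth bin up to >40 is
    populated), one background domain hit per protein on average.
    """

    seed: int = 0
    n_proteins: int = 500
    n_actins: int = 6
    n_true_aaps: int = 120
    n_tissues: int = 50
    mean_background_domains: float = 1.0
    score_noise: float = 1.0  # width fraction of the score bands around thresholds
    evidence_mix: Mapping[str, float] = field(default_factory=_default_mix)
    isoform_fraction: float = 0.15
    databases: tuple[str, ...] = tuple(sorted(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.n_actins < 1 or self.n_actins > self.n_proteins:
            raise ConfigurationError("n_actins must be in [1, n_proteins]")
        if not (0 <= self.n_true_aaps <= self.n_proteins - self.n_actins):
            raise ConfigurationError(
                "n_true_aaps must satisfy 0 <= n_true_aaps <= n_proteins - n_actins"
            )
        if self.n_tissues < 1:
            raise ConfigurationError("n_tissues must be >= 1")
        if self.mean_background_domains < 0:
            raise ConfigurationError("mean_background_domains must be >= 0")
        for name in ("score_noise", "isoform_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        unknown = set(self.evidence_mix) - set(_default_mix())
        if unknown:
            raise ConfigurationError(f"evidence_mix has unknown source(s): {sorted(unknown)}")
        for key, frac in self.evidence_mix.items():
            if not (0 <= frac <= 1):
                raise ConfigurationError(f"evidence_mix[{key!r}] must be in [0, 1]")
        for db in self.databases:
            if db not in DEFAULT_THRESHOLDS:
                raise ConfigurationError(f"unknown database {db!r} in databases")


@dataclass(frozen=True)
class GroundTruth:
    """Planted AAPs and the evidence sources planned for each."""

    true_aap_accessions: frozenset[str]
    evidence_plan: Mapping[str, frozenset[str]]

    def per_source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sources in self.evidence_plan.values():
            for s in sources:
                counts[s] = counts.get(s, 0) + 1
        return dict(sorted(counts.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"accession": acc, "sources": ";".join(sorted(self.evidence_plan[acc]))}
            for acc in sorted(self.true_aap_accessions)
        ]
        return pd.DataFrame(rows, columns=["accession", "sources"])


@dataclass
class SyntheticProteome:
    """In-memory synthetic universe: metadata, sequences, truth, and plans."""

    config: SimulationConfig
    metadata: pd.DataFrame
    sequences: dict[str, str]  # includes isoform records
    actins: tuple[str, ...]
    ground_truth: GroundTruth
    hit_rows: list[dict]  # fully planned domain-hit table rows
    edge_plan: list[tuple[str, str, str]]  # (database, actin, protein) planted edges
    decoys: dict[str, str]  # rejection-path decoy label -> accession
    literature: tuple[str, ...]
    pdb_curated: tuple[str, ...]

    @property
    def accessions(self) -> list[str]:
        return list(self.metadata["accession"])


def _accession(i: int) -> str:
    return f"SYN{i:05d}"


def _log_uniform(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10 ** rng.uniform(lo_exp, hi_exp))


class _HitPlanner:
    """Places hits left-to-right with >tolerance gaps so planted hits never conflict."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.cursor: dict[str, int] = {}
        self.rows: list[dict] = []

    def place(
        self,
        protein: str,
        family: str,
        passing: bool = True,
        coverage: float | None = None,
        evalue: float | None = None,
        overlap_prev: int = 0,
    ) -> dict:
        model_length = MODEL_LENGTHS[family]
        if coverage is None:
            coverage = float(self.rng.uniform(0.75, 1.0)) if passing else 1.0
        hmm_span = max(1, int(round(coverage * model_length)))
        ali_span = hmm_span + int(self.rng.integers(-3, 4))
        ali_span = max(5, ali_span)
        start = self.cursor.get(protein, 1)
        if overlap_prev > 0:
            # cursor sits 27 past the previous hit's end; reach back so that
            # this hit overlaps the previous one by exactly overlap_prev residues
            start = max(1, start - 26 - overlap_prev)
        if evalue is None:
            evalue = (
                _log_uniform(self.rng, -12, -3.5) if passing else _log_uniform(self.rng, -2.9, -1.8)
            )
        row = {
            "protein": protein,
            "family": family,
            "clan": "",
            "ali_from": start,
            "ali_to": start + ali_span - 1,
            "hmm_from": 1,
            "hmm_to": hmm_span,
            "model_length": model_length,
            "full_sequence_evalue": evalue * float(self.rng.uniform(0.1, 1.0)),
            "independent_evalue": evalue,
            "bit_score": round(float(self.rng.uniform(20, 300)), 1),
        }
        self.rows.append(row)
        end = row["ali_to"]
        self.cursor[protein] = max(self.cursor.get(protein, 1), end + 27)
        return row


def _plan_evidence(
    rng: np.random.Generator, config: SimulationConfig, planted: list[str]
) -> dict[str, frozenset[str]]:
    mix = dict(config.evidence_mix)
    plan: dict[str, frozenset[str]] = {}
    positive = [k for k, v in mix.items() if v > 0]
    for acc in planted:
        sources: set[str] = set()
        for key in sorted(mix):
            if rng.random() < mix[key]:
                if key == "ppi":
                    k = int(rng.integers(1, 4))
                    dbs = rng.choice(config.databases, size=min(k, len(config.databases)), replace=False)
                    sources.update(f"ppi:{db}" for db in sorted(dbs))
                else:
                    sources.add(_MIX_TO_SOURCE[key])
        if not sources and positive:
            weights = np.array([mix[k] for k in positive])
            key = str(rng.choice(positive, p=weights / weights.sum()))
            if key == "ppi":
                sources.add(f"ppi:{rng.choice(config.databases)}")
            else:
                sources.add(_MIX_TO_SOURCE[key])
        plan[acc] = frozenset(sources)
    return plan


def simulate_proteome(config: SimulationConfig) -> SyntheticProteome:
    """Build the synthetic universe: accessions, truth plan, metadata, sequences.

    All downstream simulators draw from plans fixed here, so they can be
    called in any order and remain deterministic for a given configuration.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n = config.n_proteins
    accessions = [_accession(i) for i in range(1, n + 1)]
    actins = tuple(accessions[: config.n_actins])
    others = accessions[config.n_actins:]
    planted = sorted(rng.choice(others, size=config.n_true_aaps, replace=False).tolist())
    plan = _plan_evidence(rng, config, planted)
    true_set = frozenset(a for a in planted if plan[a])
    truth = GroundTruth(true_aap_accessions=true_set, evidence_plan=plan)

    non_planted = [a for a in others if a not in set(planted)]
    decoys: dict[str, str] = {}
    for label, acc in zip(
        ("bad_evalue", "bad_coverage", "overlap_evicted", "ppi_decoy"), non_planted
    ):
        decoys[label] = acc

    # --- domain-hit plan ----------------------------------------------------
    planner = _HitPlanner(rng)
    isoform_of: dict[str, str] = {}
    for acc in planted:
        sources = plan[acc]
        if "pfam_domain" in sources:
            fam = str(rng.choice(ABD_FAMILIES))
            planner.place(acc, fam, passing=True)
            if rng.random() < config.isoform_fraction:
                iso = f"{acc}-2"
                isoform_of[iso] = acc
                planner.place(iso, fam, passing=True)
        if "go:pfam2go" in sources:
            planner.place(acc, str(rng.choice(_PFAM2GO_ACTIN)), passing=True)
    # background neutral hits everywhere
    for acc in accessions:
        for _ in range(int(rng.poisson(config.mean_background_domains))):
            planner.place(acc, str(rng.choice(NEUTRAL_FAMILIES)), passing=True)
    # rejection-path decoys, one failure mode each
    if "bad_evalue" in decoys:
        planner.place(decoys["bad_evalue"], "CH", passing=False, coverage=1.0)
    if "bad_coverage" in decoys:
        planner.place(decoys["bad_coverage"], "CH", passing=True, coverage=0.6, evalue=1e-8)
    if "overlap_evicted" in decoys:
        acc = decoys["overlap_evicted"]
        planner.place(acc, "Pkinase", passing=True, coverage=1.0, evalue=1e-10)
        # ABD hit overlapping the stronger neutral hit by 30 residues: evicted
        planner.place(acc, "CH", passing=True, coverage=1.0, evalue=1e-5, overlap_prev=30)

    # --- metadata -----------------------------------------------------------
    base_lengths = rng.integers(300, 1200, size=n)
    rows = []
    for acc, base_len in zip(accessions, base_lengths):
        length = max(int(base_len), planner.cursor.get(acc, 1) + 30)
        go_terms = sorted(
            rng.choice(NEUTRAL_GO_TERMS, size=int(rng.integers(1, 5)), replace=False).tolist()
        )
        if acc in plan and "go:uniprot" in plan[acc]:
            go_terms.append(str(rng.choice(ACTIN_GO_TERMS)))
        loc_draw = rng.random()
        lipidation = ""
        transmembrane = intramembrane = topological_domain = 0
        if acc in actins:
            location = "Cytoplasm, cytoskeleton"
        elif loc_draw < 0.12:
            location = "Cell membrane"
            flag = int(rng.integers(0, 3))
            transmembrane = int(flag == 0)
            intramembrane = int(flag == 1)
            topological_domain = int(flag == 2)
            if rng.random() < 0.2:  # integral takes precedence over lipidation
                lipidation = str(rng.choice(["Palmitoylation", "Myristoylation"]))
        elif loc_draw < 0.18:
            location = "Cell membrane; Peripheral membrane protein"
        elif loc_draw < 0.26:
            n_mods = 2 if rng.random() < 0.15 else 1
            mods = rng.choice(
                ["Farnesylation", "Myristoylation", "Palmitoylation", "Geranylgeranylation"],
                size=n_mods,
                replace=False,
            )
            lipidation = ";".join(sorted(mods.tolist()))
            location = "Cell membrane"
        elif loc_draw < 0.71:
            location = str(rng.choice(["Cytoplasm", "Cytoplasm, cytoskeleton"]))
        else:
            location = str(rng.choice(["Nucleus", "Mitochondrion", "Endoplasmic reticulum"]))
        rows.append(
            {
                "accession": acc,
                "gene_name": f"GENE{acc[3:]}",
                "length": length,
                "go_terms": ";".join(go_terms),
                "subcellular_location": location,
                "lipidation": lipidation,
                "transmembrane": transmembrane,
                "intramembrane": intramembrane,
                "topological_domain": topological_domain,
            }
        )
    metadata = pd.DataFrame(rows)
    lengths = dict(zip(metadata["accession"], metadata["length"]))

    # --- sequences (random residues; isoforms share the parent length) ------
    sequences: dict[str, str] = {}
    for acc in accessions:
        L = int(lengths[acc])
        sequences[acc] = "".join(rng.choice(list(_AA), size=L).tolist())
    for iso, parent in sorted(isoform_of.items()):
        L = max(int(lengths[parent]) - int(rng.integers(0, 40)), planner.cursor.get(iso, 1) + 30)
        sequences[iso] = "".join(rng.choice(list(_AA), size=L).tolist())

    # --- interaction-edge plan ----------------------------------------------
    edge_plan = []
    for acc in planted:
        for source in sorted(plan[acc]):
            if source.startswith("ppi:"):
                db = source.split(":", 1)[1]
                edge_plan.append((db, str(rng.choice(actins)), acc))

    literature = tuple(sorted(a for a in planted if "literature" in plan[a]))
    pdb_curated = tuple(sorted(a for a in planted if "go:pdb" in plan[a]))

    return SyntheticProteome(
        config=config,
        metadata=metadata,
        sequences=sequences,
        actins=actins,
        ground_truth=truth,
        hit_rows=planner.rows,
        edge_plan=edge_plan,
        decoys=decoys,
        literature=literature,
        pdb_curated=pdb_curated,
    )


def simulate_domain_hits(proteome: SyntheticProteome) -> pd.DataFrame:
    """Materialize the planned HMM-scan-style hit table (native TSV dialect)."""
    columns = [
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
    ]
    df = pd.DataFrame(proteome.hit_rows, columns=columns)
    return df.sort_values(["protein", "ali_from", "family"], kind="stable").reset_index(drop=True)


def simulate_ppi_edges(proteome: SyntheticProteome) -> dict[str, pd.DataFrame]:
    """One edge table per database: planted supra-threshold physical edges plus decoys."""
    config = proteome.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    non_actins = [a for a in proteome.accessions if a not in set(proteome.actins)]
    # decoy edges avoid planted AAPs so every planted (protein, database) pair
    # has exactly one qualifying edge and decoy proteins have none
    decoy_pool = [
        a for a in non_actins if a not in proteome.ground_truth.true_aap_accessions
    ] or non_actins
    tables: dict[str, list[dict]] = {db: [] for db in config.databases}
    noise = max(config.score_noise, 1e-6)

    def planted_score(db: str) -> tuple[float, float | None]:
        rule = DEFAULT_THRESHOLDS[db]
        lo = rule.score_min if rule.score_min is not None else 0.0
        band = (rule.scale_max - lo) * noise
        score = rule.scale_max - float(rng.uniform(0, 0.95)) * band
        score2 = None
        if rule.score2_min is not None:
            score2 = rule.score2_min + (1.0 - rule.score2_min) * float(rng.uniform(0.05, 1.0))
        return round(score, 4), None if score2 is None else round(score2, 4)

    def decoy_score(db: str) -> tuple[float, float | None, str]:
        """A score/type combination guaranteed to fail the database's rule."""
        rule = DEFAULT_THRESHOLDS[db]
        if rule.score_min is None:
            # no score filter: only the physical-type rule can reject
            return round(float(rng.uniform(0, rule.scale_max)), 4), None, "functional"
        if rng.random() < 0.5:
            score = rule.score_min * (1.0 - float(rng.uniform(0, 0.95)) * noise)
            score2 = rule.score2_min  # at-threshold secondary also fails (strict >)
            return round(score, 4), score2, "physical"
        score, score2 = planted_score(db)
        return score, score2, "functional"

    for db, actin, protein in proteome.edge_plan:
        score, score2 = planted_score(db)
        row = {"a": actin, "b": protein, "score": score, "interaction_type": "physical"}
        if score2 is not None:
            row["score2"] = score2
        tables[db].append(row)

    n_decoy = max(3, config.n_proteins // 25)
    for db in config.databases:
        rule = DEFAULT_THRESHOLDS[db]
        for _ in range(n_decoy):
            target = str(rng.choice(decoy_pool)) if decoy_pool else proteome.actins[0]
            score, score2, itype = decoy_score(db)
            row = {
                "a": str(rng.choice(proteome.actins)),
                "b": target,
                "score": score,
                "interaction_type": itype,
            }
            if rule.score2_min is not None:
                row["score2"] = score2 if score2 is not None else 0.0
            tables[db].append(row)
        # an actin-actin edge that passes the score rule but must not enter the census
        if len(proteome.actins) >= 2:
            score, score2 = planted_score(db)
            row = {
                "a": proteome.actins[0],
                "b": proteome.actins[1],
                "score": score,
                "interaction_type": "physical",
            }
            if rule.score2_min is not None:
                row["score2"] = score2
            tables[db].append(row)
        # bystander edge not touching any actin: never inspected
        if len(non_actins) >= 2:
            pair = rng.choice(non_actins, size=2, replace=False)
            row = {
                "a": str(pair[0]),
                "b": str(pair[1]),
                "score": round(float(rng.uniform(0, rule.scale_max)), 4),
                "interaction_type": "physical",
            }
            if rule.score2_min is not None:
                row["score2"] = round(float(rng.uniform(0.5, 1.0)), 4)
            tables[db].append(row)

    out = {}
    for db in config.databases:
        cols = ["a", "b", "score", "interaction_type"]
        if DEFAULT_THRESHOLDS[db].score2_min is not None:
            cols.append("score2")
        df = pd.DataFrame(tables[db], columns=cols)
        out[db] = df.sort_values(["a", "b", "score"], kind="stable").reset_index(drop=True)
    return out


def simulate_expression(proteome: SyntheticProteome) -> pd.DataFrame:
    """Tissue-expression table with controlled breadth classes and filter bait.

    The first non-actin proteins are pinned to breadth 1, 2-5, and >40 (when
    the tissue count permits) so every histogram bin is populated; rows with
    ``uncertain`` reliability or ``not_detected`` level are planted in tissues
    outside a protein's retained set, so filtering them out is observable.
    """
    config = proteome.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    tissues = [f"tissue_{i:02d}" for i in range(1, config.n_tissues + 1)]
    rows = []
    non_actins = [a for a in proteome.accessions if a not in set(proteome.actins)]
    pinned: dict[str, int] = {}
    if non_actins:
        pinned[non_actins[0]] = 1
    if len(non_actins) > 1 and config.n_tissues >= 2:
        pinned[non_actins[1]] = min(3, config.n_tissues)
    if len(non_actins) > 2 and config.n_tissues > 40:
        pinned[non_actins[2]] = min(45, config.n_tissues)

    for acc in proteome.accessions:
        if acc in pinned:
            breadth = pinned[acc]
        else:
            draw = rng.random()
            if draw < 0.06:
                breadth = 0  # no expression data
            elif draw < 0.12:
                breadth = 1
            elif draw < 0.62:
                breadth = int(rng.integers(2, 6))
            elif draw < 0.92 or config.n_tissues <= 40:
                breadth = int(rng.integers(6, 41))
            else:
                breadth = int(rng.integers(41, config.n_tissues + 1))
        breadth = min(breadth, config.n_tissues)
        chosen = rng.choice(tissues, size=breadth, replace=False).tolist() if breadth else []
        for t in sorted(chosen):
            rows.append(
                {
                    "protein": acc,
                    "tissue": t,
                    "level": str(rng.choice(["high", "medium", "low"], p=[0.3, 0.45, 0.25])),
                    "reliability": str(rng.choice(["enhanced", "supported", "approved"])),
                }
            )
        unused = sorted(set(tissues) - set(chosen))
        if unused and rng.random() < 0.2:
            t = unused.pop(int(rng.integers(0, len(unused))))
            rows.append(
                {"protein": acc, "tissue": t, "level": "high", "reliability": "uncertain"}
            )
        if unused and rng.random() < 0.2:
            t = unused.pop(int(rng.integers(0, len(unused))))
            rows.append(
                {"protein": acc, "tissue": t, "level": "not_detected", "reliability": "approved"}
            )
    df = pd.DataFrame(rows, columns=["protein", "tissue", "level", "reliability"])
    return df.sort_values(["protein", "tissue", "reliability"], kind="stable").reset_index(
        drop=True
    )


def simulate_cog(proteome: SyntheticProteome) -> pd.DataFrame:
    """Ortholog/COG table: mostly single-letter categories, some multi-letter."""
    config = proteome.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    letters = list(COG_LETTERS)
    weights = np.ones(len(letters))
    for favored in "TZKOUAS":
        weights[letters.index(favored)] = 6.0
    weights /= weights.sum()
    rows = []
    for acc in proteome.accessions:
        draw = rng.random()
        if draw < 0.03:
            continue  # no ortholog information
        n_cats = 2 if draw > 0.95 else 1
        cats = rng.choice(letters, size=n_cats, replace=False, p=weights)
        rows.append(
            {
                "protein": acc,
                "categories": "".join(sorted(cats.tolist())),
                "taxonomic_level": str(rng.choice(["Metazoa", "Eukaryota"], p=[0.9, 0.1])),
            }
        )
    return pd.DataFrame(rows, columns=["protein", "categories", "taxonomic_level"])


def _write_lines(path: Path, lines) -> None:
    path.write_text("".join(f"{line}\n" for line in lines))


def simulate_all(config: SimulationConfig, outdir: str | Path, force: bool = False) -> dict[str, Path]:
    """Generate and write every synthetic input file under ``outdir``.

    Returns a name -> path map of everything written.  Refuses to overwrite
    an existing fixture set unless ``force`` is given.
    """
    outdir = Path(outdir)
    sentinel = outdir / "metadata.tsv"
    if sentinel.exists() and not force:
        raise ConfigurationError(f"{outdir} already contains fixtures (use force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "edges").mkdir(exist_ok=True)

    proteome = simulate_proteome(config)
    paths: dict[str, Path] = {}

    fasta = outdir / "proteome.fasta"
    records = [
        SeqRecord(Seq(proteome.sequences[acc]), id=acc, description="synthetic")
        for acc in sorted(proteome.sequences)
    ]
    SeqIO.write(records, str(fasta), "fasta")
    paths["fasta"] = fasta

    proteome.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.tsv"

    simulate_domain_hits(proteome).to_csv(outdir / "domain_hits.tsv", sep="\t", index=False)
    paths["domain_hits"] = outdir / "domain_hits.tsv"

    for db, df in simulate_ppi_edges(proteome).items():
        p = outdir / "edges" / f"{db}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"edges:{db}"] = p

    simulate_expression(proteome).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    paths["expression"] = outdir / "expression.tsv"

    simulate_cog(proteome).to_csv(outdir / "cog.tsv", sep="\t", index=False)
    paths["cog"] = outdir / "cog.tsv"

    proteome.ground_truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    paths["ground_truth"] = outdir / "ground_truth.tsv"

    _write_lines(outdir / "actins.txt", proteome.actins)
    _write_lines(outdir / "abd_families.txt", ABD_FAMILIES)
    _write_lines(outdir / "actin_go_terms.txt", ACTIN_GO_TERMS)
    _write_lines(
        outdir / "pfam2go.tsv",
        [f"{fam}\t{term}" for fam in sorted(PFAM2GO) for term in PFAM2GO[fam]],
    )
    _write_lines(outdir / "clan_map.tsv", [f"{f}\t{c}" for f, c in sorted(CLAN_MAP.items())])
    _write_lines(outdir / "literature.txt", proteome.literature)
    _write_lines(outdir / "pdb_curated.txt", proteome.pdb_curated)
    for name in (
        "actins",
        "abd_families",
        "actin_go_terms",
        "pfam2go",
        "clan_map",
        "literature",
        "pdb_curated",
    ):
        suffix = ".tsv" if name in ("pfam2go", "clan_map") else ".txt"
        paths[name] = outdir / f"{name}{suffix}"
    return paths
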