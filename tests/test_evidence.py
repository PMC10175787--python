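"""Interaction/domain/GO evidence harvesting and census assembly."""

import pandas as pd
import pytest

from aapcensus.domains import DomainArchitecture
from aapcensus.errors import ConfigurationError, FormatError, UsageError
from aapcensus.evidence import (
    DEFAULT_THRESHOLDS,
    EvidenceRecord,
    PPIEdge,
    build_census,
    canonical_accession,
    census_to_frame,
    domain_evidence,
    go_evidence,
    ppi_evidence,
    read_edge_file,
)

from conftest import make_hit

ACTINS = ["ACT01", "ACT02"]


def edge(db, a="ACT01", b="X1", score=0.9, itype="physical", score2=None):
    return PPIEdge(a=a, b=b, database=db, score=score, interaction_type=itype, score2=score2)


def harvest(edges_by_db, **kw):
    return ppi_evidence(edges_by_db, ACTINS, **kw)


class TestPPIEvidence:
    def test_string_edge_above_700_yields_record(self):
        recs = harvest({"string": [edge("string", score=850)]})
        assert [(r.protein, r.source, r.detail) for r in recs] == [("X1", "ppi:string", "ACT01")]

    def test_threshold_is_strict_at_equality(self):
        assert harvest({"mentha": [edge("mentha", score=0.6)]}) == []
        assert len(harvest({"mentha": [edge("mentha", score=0.6 + 1e-9)]})) == 1

    def test_hitpredict_requires_both_scores(self):
        assert harvest({"hitpredict": [edge("hitpredict", score=0.7, score2=0.40)]}) == []
        assert harvest({"hitpredict": [edge("hitpredict", score=0.7, score2=None)]}) == []
        assert len(harvest({"hitpredict": [edge("hitpredict", score=0.7, score2=0.5)]})) == 1

    def test_non_physical_edges_never_yield_evidence(self):
        for db in DEFAULT_THRESHOLDS:
            top = DEFAULT_THRESHOLDS[db].scale_max * 0.99
            assert harvest({db: [edge(db, score=top, itype="functional", score2=0.99)]}) == []

    def test_no_threshold_databases_accept_any_physical_score(self):
        for db in ("dip", "hint", "huri"):
            assert len(harvest({db: [edge(db, score=0.01)]})) == 1

    def test_actin_partners_excluded_by_default(self):
        edges = {"string": [edge("string", a="ACT01", b="ACT02", score=900)]}
        assert harvest(edges) == []
        assert len(harvest(edges, include_actins=True)) == 2  # both directions

    def test_unknown_database_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="nosuchdb"):
            harvest({"nosuchdb": [edge("nosuchdb")]})

    def test_score_outside_scale_is_format_error(self):
        with pytest.raises(FormatError, match="scale"):
            harvest({"mentha": [edge("mentha", score=1.5)]})

    def test_edges_not_touching_actins_ignored(self):
        assert harvest({"string": [edge("string", a="Y1", b="Y2", score=999)]}) == []

    def test_isoform_partner_collapsed_to_canonical(self):
        recs = harvest({"string": [edge("string", b="X7-2", score=800)]})
        assert recs[0].protein == "X7"


class TestDomainEvidence:
    def arch(self, protein, families):
        hits = tuple(
            make_hit(protein=protein, family=f, ali_from=1 + 200 * i, ali_to=100 + 200 * i)
            for i, f in enumerate(families)
        )
        return DomainArchitecture(protein=protein, domains=hits)

    def test_abd_membership_yields_one_record(self):
        archs = {"P1": self.arch("P1", ["CH", "SH3_1"]), "P2": self.arch("P2", ["PH"])}
        recs = domain_evidence(archs, ["CH", "VHP"])
        assert [(r.protein, r.source, r.detail) for r in recs] == [("P1", "pfam_domain", "CH")]

    def test_empty_abd_list_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            domain_evidence({}, [])

    def test_evidence_uses_accepted_domains_only(self):
        # the ABD hit is absent from the accepted architecture: no record
        archs = {"P1": self.arch("P1", ["PH"])}
        assert domain_evidence(archs, ["CH"]) == []


class TestGOEvidence:
    TERMS = ["GO:0003779", "GO:0015629"]

    def test_uniprot_annotation_membership(self):
        meta = pd.DataFrame(
            [
                {"accession": "P1", "go_terms": "GO:0005515;GO:0003779"},
                {"accession": "P2", "go_terms": "GO:0005515"},
            ]
        )
        recs = go_evidence("go:uniprot", self.TERMS, metadata=meta)
        assert [(r.protein, r.detail) for r in recs] == [("P1", "GO:0003779")]

    def test_pfam2go_route_through_accepted_families(self):
        archs = {"P1": TestDomainEvidence().arch("P1", ["WH2"])}
        recs = go_evidence(
            "go:pfam2go", self.TERMS, pfam2go={"WH2": {"GO:0003779"}}, architectures=archs
        )
        assert [(r.protein, r.source) for r in recs] == [("P1", "go:pfam2go")]

    def test_pdb_curated_list(self):
        recs = go_evidence("go:pdb", self.TERMS, curated_list=["P9", "P3"])
        assert [r.protein for r in recs] == ["P3", "P9"]

    def test_sources_are_independent(self):
        meta = pd.DataFrame([{"accession": "P1", "go_terms": "GO:0003779"}])
        archs = {"P1": TestDomainEvidence().arch("P1", ["WH2"])}
        uni = go_evidence("go:uniprot", self.TERMS, metadata=meta)
        p2g = go_evidence("go:pfam2go", self.TERMS, pfam2go={"WH2": {"GO:0003779"}},
                          architectures=archs)
        assert {r.source for r in uni + p2g} == {"go:uniprot", "go:pfam2go"}

    def test_unknown_tag_and_empty_terms_rejected(self):
        with pytest.raises(UsageError):
            go_evidence("go:bogus", self.TERMS)
        with pytest.raises(ConfigurationError):
            go_evidence("go:pdb", [], curated_list=["P1"])


class TestBuildCensus:
    def test_union_of_sources_per_protein(self):
        streams = [
            [EvidenceRecord("P1", "ppi:string", "ACT01")],
            [EvidenceRecord("P1", "pfam_domain", "CH")],
        ]
        (entry,) = build_census(streams)
        assert entry.sources == {"ppi:string", "pfam_domain"}
        assert len(entry.records) == 2

    def test_isoforms_collapse_to_canonical(self):
        streams = [
            [EvidenceRecord("SYN00007", "ppi:string", "ACT01")],
            [EvidenceRecord("SYN00007-2", "pfam_domain", "CH")],
        ]
        (entry,) = build_census(streams)
        assert entry.protein == "SYN00007"
        assert entry.sources == {"ppi:string", "pfam_domain"}

    def test_literature_list_added_as_own_source(self):
        entries = build_census([[EvidenceRecord("P1", "ppi:dip", "ACT01")]], ["P2", "P1"])
        by = {e.protein: e.sources for e in entries}
        assert by == {"P1": {"ppi:dip", "literature"}, "P2": {"literature"}}

    def test_excluded_accessions_dropped(self):
        entries = build_census(
            [[EvidenceRecord("ACT01", "go:uniprot", "GO:0003779"),
              EvidenceRecord("P1", "go:uniprot", "GO:0003779")]],
            exclude=ACTINS,
        )
        assert [e.protein for e in entries] == ["P1"]

    def test_union_bounds(self):
        streams = [
            [EvidenceRecord(f"P{i}", "ppi:string", "ACT01") for i in range(5)],
            [EvidenceRecord(f"P{i}", "pfam_domain", "CH") for i in range(3, 8)],
        ]
        entries = build_census(streams)
        per_source = [5, 5]
        assert max(per_source) <= len(entries) <= sum(per_source)
        # provenance conservation: each record's protein in exactly one entry
        seen = [e.protein for e in entries]
        assert len(seen) == len(set(seen))

    def test_frame_round_trip(self):
        entries = build_census([[EvidenceRecord("P1", "ppi:string", "ACT01")]])
        frame = census_to_frame(entries)
        assert list(frame.columns) == ["protein", "sources", "n_sources"]
        assert frame.iloc[0]["n_sources"] == 1


def test_canonical_accession():
    assert canonical_accession("SYN00007-2") == "SYN00007"
    assert canonical_accession("SYN00007") == "SYN00007"


def test_read_edge_file_rejects_bad_interaction_type(tmp_path):
    p = tmp_path / "string.tsv"
    p.write_text("a\tb\tscore\tinteraction_type\nACT01\tX1\t900\tgenetic\n")
    with pytest.raises(FormatError, match="genetic"):
        read_edge_file(p)
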