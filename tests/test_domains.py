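"""Domain-hit parsing, filtering, and greedy overlap resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aapcensus.domains import (
    HIT_COLUMNS,
    DomainArchitecture,
    FilterConfig,
    assign_clans,
    filter_hits,
    overlap,
    parse_hits,
    read_clan_map,
    resolve_architecture,
    resolve_architectures,
)
from aapcensus.errors import ConfigurationError, FormatError, UsageError

from conftest import hit_key, make_hit, naive_resolve, random_hits


def _write_hits(path, rows):
    lines = ["\t".join(HIT_COLUMNS)]
    for r in rows:
        lines.append("\t".join(str(r.get(c, "")) for c in HIT_COLUMNS))
    path.write_text("\n".join(lines) + "\n")


ROW = dict(
    protein="SYN00010",
    family="CH",
    clan="CL0188",
    ali_from=10,
    ali_to=110,
    hmm_from=1,
    hmm_to=100,
    model_length=110,
    full_sequence_evalue=1e-8,
    independent_evalue=1e-7,
    bit_score=55.2,
)


class TestParseHits:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        p = tmp_path / "hits.tsv"
        _write_hits(p, [ROW, {**ROW, "family": "PH", "ali_from": 200, "ali_to": 290},
                        {**ROW, "protein": "SYN00011"}])
        hits = parse_hits(p)
        assert len(hits) == 3
        assert hits[0].family == "CH" and hits[0].clan == "CL0188"
        assert hits[0].model_coverage == pytest.approx(100 / 110)

    def test_header_only_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "hits.tsv"
        _write_hits(p, [])
        assert parse_hits(p) == []

    @pytest.mark.parametrize(
        "bad, message",
        [
            ({"ali_from": 120, "ali_to": 110}, "row 1"),  # inverted coordinates
            ({"independent_evalue": "not-a-number"}, "row 1"),
            ({"independent_evalue": 0.0}, "row 1"),  # E-values must be positive
            ({"hmm_to": 200}, "row 1"),  # exceeds model length
        ],
    )
    def test_malformed_row_reports_row_number(self, tmp_path, bad, message):
        p = tmp_path / "hits.tsv"
        _write_hits(p, [{**ROW, **bad}])
        with pytest.raises(FormatError, match=message):
            parse_hits(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        cols = [c for c in HIT_COLUMNS if c != "bit_score"]
        p.write_text("\t".join(cols) + "\n")
        with pytest.raises(FormatError, match="bit_score"):
            parse_hits(p)

    def test_domtblout_dialect_maps_columns_by_position(self, tmp_path):
        # 22-column space-delimited per-domain scanner output + description
        line = (
            "CH PF00307.32 110 SYN00010 - 500 1e-8 60.1 0.2 1 2 1e-9 1e-7 "
            "55.2 0.1 1 100 10 110 5 115 0.98 Calponin homology domain"
        )
        p = tmp_path / "scan.domtblout"
        p.write_text("# comment line\n" + line + "\n")
        (hit,) = parse_hits(p, dialect="domtblout")
        assert hit.protein == "SYN00010"
        assert hit.family == "PF00307.32"
        assert (hit.ali_from, hit.ali_to) == (10, 110)
        assert (hit.hmm_from, hit.hmm_to, hit.model_length) == (1, 100, 110)
        assert hit.independent_evalue == pytest.approx(1e-7)


class TestFilterHits:
    @pytest.mark.parametrize(
        "ie, hmm_from, hmm_to, model_length, kept",
        [
            (5e-4, 1, 90, 100, True),  # both filters pass
            (5e-4, 1, 60, 100, False),  # coverage 0.60 < 0.7
            (0.01, 1, 100, 100, False),  # 0.01 > 0.001
            (0.001, 1, 100, 100, True),  # at the E-value boundary: retained
            (1e-6, 1, 70, 100, True),  # coverage exactly 0.7: retained
            (1e-6, 31, 100, 100, True),  # coverage from interior model span
        ],
    )
    def test_evalue_and_coverage_boundaries(self, ie, hmm_from, hmm_to, model_length, kept):
        h = make_hit(ie=ie, hmm_from=hmm_from, hmm_to=hmm_to,
                     model_length=model_length, ali_to=hmm_to - hmm_from + 1)
        assert (filter_hits([h]) == [h]) is kept

    def test_order_preserved(self):
        hits = [make_hit(family=f, ie=e) for f, e in [("A1", 1e-4), ("B1", 1e-9), ("C1", 1e-5)]]
        assert [h.family for h in filter_hits(hits)] == ["A1", "B1", "C1"]

    @given(st.floats(min_value=1e-8, max_value=1e-2), st.floats(min_value=0.3, max_value=1.0))
    @settings(max_examples=60, derandomize=True)
    def test_tightening_filters_never_adds_hits(self, ie_max, cov_min):
        rng = np.random.default_rng(42)
        hits = random_hits(rng, 15)
        loose = FilterConfig(independent_evalue_max=ie_max, model_coverage_min=cov_min)
        tight = FilterConfig(independent_evalue_max=ie_max / 2,
                             model_coverage_min=min(1.0, cov_min + 0.1))
        assert set(map(hit_key, filter_hits(hits, tight))) <= set(
            map(hit_key, filter_hits(hits, loose))
        )


class TestResolveArchitecture:
    def test_single_hit_architecture(self):
        h = make_hit()
        arch = resolve_architecture([h])
        assert arch.families == ("CH",)
        assert arch.architecture_string == "CH"

    def test_lowest_evalue_wins_on_30_residue_overlap(self):
        strong = make_hit(family="CH", ali_from=1, ali_to=100, ie=1e-10)
        weak = make_hit(family="PH", ali_from=71, ali_to=170, ie=1e-5)
        arch = resolve_architecture([strong, weak])
        assert arch.families == ("CH",)

    def test_overlap_exactly_25_both_kept_26_conflicts(self):
        a = make_hit(family="CH", ali_from=1, ali_to=100, ie=1e-10)
        b25 = make_hit(family="PH", ali_from=76, ali_to=175, ie=1e-5)
        b26 = make_hit(family="PH", ali_from=75, ali_to=174, ie=1e-5)
        assert resolve_architecture([a, b25]).families == ("CH", "PH")
        assert resolve_architecture([a, b26]).families == ("CH",)

    def test_equal_evalues_break_ties_deterministically(self):
        # same E-value: the longer alignment is placed first and wins
        long = make_hit(family="PH", ali_from=1, ali_to=120, ie=1e-6,
                        hmm_to=120, model_length=120)
        short = make_hit(family="CH", ali_from=50, ali_to=130, ie=1e-6,
                         hmm_to=81, model_length=81)
        assert resolve_architecture([long, short]).families == ("PH",)
        assert resolve_architecture([short, long]).families == ("PH",)

    def test_domains_ordered_by_position_not_significance(self):
        right = make_hit(family="PH", ali_from=200, ali_to=280, ie=1e-12)
        left = make_hit(family="CH", ali_from=1, ali_to=100, ie=1e-5)
        assert resolve_architecture([right, left]).families == ("CH", "PH")

    def test_multi_protein_input_rejected(self):
        with pytest.raises(UsageError):
            resolve_architecture([make_hit(protein="A"), make_hit(protein="B")])

    def test_matches_naive_reimplementation_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            hits = random_hits(rng, int(rng.integers(1, 13)))
            got = {hit_key(h) for h in resolve_architecture(hits).domains}
            assert got == naive_resolve(hits)

    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=80, derandomize=True)
    def test_invariants_hold_on_random_instances(self, n, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, n)
        arch = resolve_architecture(hits)
        # pairwise overlap bounded by the tolerance
        for i, a in enumerate(arch.domains):
            for b in arch.domains[i + 1:]:
                assert overlap(a, b) <= 25
        # maximality: every rejected hit conflicts with a better accepted one
        accepted = set(map(hit_key, arch.domains))
        for h in hits:
            if hit_key(h) in accepted:
                continue
            assert any(
                overlap(h, a) > 25 and a.independent_evalue <= h.independent_evalue
                for a in arch.domains
            )
        # idempotence
        again = resolve_architecture(list(arch.domains))
        assert set(map(hit_key, again.domains)) == accepted


class TestClans:
    def test_assign_and_missing_families(self):
        archs = {"P1": resolve_architecture(
            [make_hit(protein="P1", family="CH"),
             make_hit(protein="P1", family="LIM", ali_from=200, ali_to=260,
                      hmm_to=55, model_length=55)]
        )}
        out = assign_clans(archs, {"CH": "CL0188"})
        clans = {d.family: d.clan for d in out["P1"].domains}
        assert clans == {"CH": "CL0188", "LIM": None}

    def test_conflicting_clan_map_is_format_error(self, tmp_path):
        p = tmp_path / "clans.tsv"
        p.write_text("CH\tCL0188\nCH\tCL0999\n")
        with pytest.raises(FormatError, match="CH"):
            read_clan_map(p)

    def test_identical_families_give_identical_architecture_string(self):
        def arch(protein):
            return resolve_architecture(
                [make_hit(protein=protein, family="CH"),
                 make_hit(protein=protein, family="PH", ali_from=300, ali_to=400)]
            )
        assert arch("P1").architecture_string == arch("P2").architecture_string == "CH~PH"


def test_resolve_architectures_groups_by_protein_and_filters_first():
    hits = [
        make_hit(protein="A"),
        make_hit(protein="B", ie=0.05),  # fails the E-value filter
        make_hit(protein="C", family="PH"),
    ]
    archs = resolve_architectures(hits)
    assert set(archs) == {"A", "C"}


def test_filter_config_validation():
    with pytest.raises(ConfigurationError):
        FilterConfig(model_coverage_min=0.0)
    with pytest.raises(ConfigurationError):
        FilterConfig(independent_evalue_max=-1)
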