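# Methods

## Scope and model

The package implements a deterministic evidence-integration procedure, not a
statistical model fit: a protein enters the census when at least one of
three evidence lines asserts actin association, and every downstream figure
(per-source counts, localization breakdown, tissue histogram, COG totals,
enrichment table) is a pure recount of the integrated tables. The only
probabilistic component is the enrichment stage (hypergeometric test with
Benjamini–Hochberg adjustment).

## Domain architectures

Input is a per-domain hit table from a profile-HMM scan (native TSV dialect
or standard 22-column space-delimited per-domain scanner output mapped by
position). Two post-scan filters apply, both inclusive at the boundary:

- independent (per-domain) E-value ≤ `independent_evalue_max` (default 10⁻³);
- model coverage `(hmm_to − hmm_from + 1) / model_length` ≥
  `model_coverage_min` (default 0.7).

The scan-stage sequence E-value (0.01) and gathering thresholds are
properties of how the hit table was produced upstream and are not re-applied.

Overlap resolution is greedy in ascending independent E-value. Overlap is
computed on **alignment** coordinates (1-based inclusive), the convention
for architecture building, as `max(0, min(ali_to) − max(ali_from) + 1)`. A
candidate is accepted iff its overlap with *every* already-accepted domain
is ≤ `overlap_tolerance` (default 25 residues: 25 is allowed, 26 conflicts);
the check is pairwise, not cumulative. Ties on E-value are broken by longer
alignment, then smaller start, then family accession — an arbitrary but
fixed order chosen purely for determinism. The accepted set is maximal
(every rejected hit conflicts with an accepted hit of lower-or-equal
E-value) and the procedure is idempotent; both properties are tested, and
the resolver is checked exactly against an independent naive
re-implementation on random instances. Overlaps within the same clan are
resolved identically to cross-clan overlaps; a clan-aware mode is a
possible future refinement.

Each sequence record (canonical or isoform, isoforms carrying a `-N`
accession suffix) gets its own architecture; census-level counting collapses
isoforms to the canonical accession.

## Evidence lines and thresholds

Per-database interaction thresholds (native scales) are: STRING-style
score > 700 of 1000; BioGRID-, IntAct-, MINT-, mentha-style > 0.6;
HIPPIE-style > 0.73; HitPredict-style annotation score > 0.5 **and**
method-based score > 0.485; DIP-, HINT-, HuRI-style no score filter
(curated high-confidence only). All inequalities are strict, read literally
from the published cutoffs. Every database requires the physical interaction
type by default (configurable per database, since some sources report a
combined functional channel). The dual HitPredict rule needs two scores per
edge; the edge dialect therefore allows an optional fifth `score2` column.

Actin query accessions are excluded from the census (an `include_actins`
flag restores them): the census targets *associated* proteins, and
actin–actin edges would otherwise dominate.

Domain evidence uses the **accepted** architecture only — a hit removed by
filtering or overlap resolution never yields evidence. GO evidence has
three tagged routes (protein-level annotation, pfam2go through accepted
families, curated structure-derived list) kept as distinct sources so
per-source counts remain meaningful; the literature list is a fourth,
directly curated source.

## Classification

Localization is a single-class call per protein: integral membrane if any
of the intramembrane / topological-domain / transmembrane annotations is
present; else peripheral membrane if the subcellular-location text names a
peripheral membrane association or the protein carries any of the four
lipid anchors (farnesyl, myristoyl, palmitoyl, geranylgeranyl); else
cytoplasmic if the location names cytoplasm or cytoskeleton; else other.
Integral wins over lipidation so the classes are disjoint; the lipid
modifications are still recorded on the call and tallied separately (a
protein with two modification types counts once per type and once in the
multi-modified tally).

Expression rows are retained iff reliability ≠ uncertain **and** level ≠
not-detected. Tissue breadth is the count of distinct tissues with a
retained row; the histogram bins 1, 2–5, 6–40, > 40 partition all proteins
with at least one retained row (the 6–40 bin exists to make the commonly
reported 1 / 2–5 / >40 bins exhaustive). Breadth = 1 serves as the
operational surrogate for "enriched in a single tissue"; no
antibody-level tissue-enrichment flag is modelled.

COG categories are single letters; multi-letter strings are split into one
category per letter. The letter → broad-group mapping (information storage
and processing: J A K L B; cellular processes and signaling: D Y V T M N Z
W U O X; metabolism: C G E F H I P Q; poorly characterized: R S) is the
standard COG functional-category table, shipped as package data.

## Enrichment

For study size n from background N, a term with K background and k study
members scores p = P(X ≥ k) under Hypergeom(N, K, n), computed with scipy's
hypergeometric survival function and verified in tests against exact
enumeration for all parameter combinations with N ≤ 30. The adjustment is
Benjamini–Hochberg step-up (the de-facto default of enrichment servers that
publish only an FDR cutoff); one-sided Fisher would give identical tails.
Terms with K = 0 are dropped rather than reported at p = 1, so uninformative
terms do not inflate the multiple-testing burden. The default report cutoff
is FDR ≤ 0.001; the pipeline uses the whole (synthetic) proteome as
background and the protein-level GO annotation as the term map.

## Synthetic universe

Defaults: 500 proteins, 6 actin queries, 120 planted AAPs, 50 tissues, one
background (neutral-family) domain hit per protein on average. The planted
fraction (~24% of the proteome) is deliberately richer than a real
proteome's AAP fraction (~10%) so every evidence source receives enough
members at desk scale; per-source discoverability fractions default to
PPI 0.70, ABD 0.30, protein-level GO 0.30, pfam2go 0.15, structure-derived
0.05, literature 0.10, with at least one source forced per planted protein
whenever any fraction is positive. Planted scores are drawn strictly above
each database's threshold and decoy scores at or below it (or with a
non-physical type for unthresholded databases), so both sides of every rule
are exercised; four dedicated decoy proteins fail exactly one domain rule
each (E-value, coverage, overlap eviction) or carry only disqualified
edges. Sequences are random residues — no stage reads residue identities —
and a fraction of domain-planted proteins receive a `-2` isoform to
exercise collapsing.

What the generator does **not** emulate: real UniProt/HPA field formats,
correlated annotation errors, score distributions of real databases,
homology structure among sequences, or incomplete/biased curation. Passing
the recovery test therefore demonstrates that the thresholds and set
operations are implemented exactly, not that the thresholds are optimal for
real data.

Determinism: all randomness flows from one integer seed through
deterministically spawned per-stage generators; identical configuration
gives byte-identical output files, which the tests assert at tree level.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 500-protein universe (20
seeds for end-to-end recovery, 10 seeds at 200 proteins for classification
recounts), 1,000 random ≤ 12-hit instances for the resolver oracle, the
complete N ≤ 30 hypergeometric parameter grid, and 500 null replicates for
FDR calibration — sizes chosen so the full suite completes in well under a
minute while covering every rule boundary exactly. Boundary behaviour is
asserted at equality (E-value exactly 10⁻³ kept, coverage exactly 0.7 kept,
overlap exactly 25 kept, scores exactly at threshold rejected). BH
adjustment clips to [0, 1] and is permutation-equivariant; empty p-value
lists return empty arrays.

## Known limitations

- Structural (SCOP-style) domain assignment, disorder/coiled-coil/signal
  peptide annotation, and ortholog mapping itself are out of scope; the
  ortholog/COG table is consumed, not computed.
- The census is only as good as its curated lists; the generator plants
  them, a real run must supply them.
- Localization classes are disjoint by construction; catalogs that count a
  protein in both cytoplasmic and membrane classes will disagree with the
  breakdown here.
- Enrichment supports generic term maps only; pathway/disease-specific
  catalogs must be supplied by the user in the two-column term-map format.
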