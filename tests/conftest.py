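import numpy as np
import pytest

from aapcensus.domains import DomainHit


def make_hit(
    protein="SYN00010",
    family="CH",
    ali_from=1,
    ali_to=100,
    hmm_from=1,
    hmm_to=100,
    model_length=100,
    ie=1e-6,
    full=1e-7,
    bit=50.0,
    clan=None,
):
    return DomainHit(
        protein=protein,
        family=family,
        clan=clan,
        ali_from=ali_from,
        ali_to=ali_to,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        model_length=model_length,
        full_sequence_evalue=full,
        independent_evalue=ie,
        bit_score=bit,
    )


def random_hits(rng: np.random.Generator, n: int, protein: str = "SYN00010"):
    """Random filtered-grade hits for one protein, with frequent overlaps."""
    hits = []
    families = ["CH", "PH", "SH3_1", "LIM", "Pkinase", "RRM_1", "PDZ", "VHP"]
    for i in range(n):
        start = int(rng.integers(1, 400))
        span = int(rng.integers(20, 150))
        ml = int(rng.integers(span, span + 40))
        hits.append(
            make_hit(
                protein=protein,
                family=families[int(rng.integers(0, len(families)))],
                ali_from=start,
                ali_to=start + span - 1,
                hmm_from=1,
                hmm_to=ml,
                model_length=ml,
                ie=float(10 ** rng.uniform(-12, -3.5)),
            )
        )
    return hits


def naive_resolve(hits, tolerance=25):
    """Independent O(n^2) restatement of the greedy overlap resolution.

    Repeatedly removes the most significant remaining hit (ties: longer
    alignment, smaller start, family name) and accepts it if it overlaps no
    accepted hit by more than the tolerance.
    """
    remaining = list(hits)
    accepted = []
    while remaining:
        best = min(
            remaining,
            key=lambda h: (
                h.independent_evalue,
                -(h.ali_to - h.ali_from + 1),
                h.ali_from,
                h.family,
            ),
        )
        remaining.remove(best)
        ok = True
        for a in accepted:
            ov = min(a.ali_to, best.ali_to) - max(a.ali_from, best.ali_from) + 1
            if ov > tolerance:
                ok = False
                break
        if ok:
            accepted.append(best)
    return {(h.family, h.ali_from, h.ali_to, h.independent_evalue) for h in accepted}


def hit_key(h):
    return (h.family, h.ali_from, h.ali_to, h.independent_evalue)


@pytest.fixture(scope="session")
def small_config():
    from aapcensus.fixtures import SimulationConfig

    return SimulationConfig(seed=7, n_proteins=80, n_actins=3, n_true_aaps=20, n_tissues=12)
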