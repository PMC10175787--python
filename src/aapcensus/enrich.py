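"""Hypergeometric term enrichment with Benjamini–Hochberg FDR control.

For a study set of n proteins drawn from a background of N, a term annotating
K background proteins and k study proteins is scored with the upper-tail
hypergeometric probability

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

(equivalently a one-sided Fisher exact test).  p-values are adjusted across
terms by the Benjamini–Hochberg step-up procedure; the default report cutoff
is FDR <= 0.001.  Terms with no background annotation (K = 0) are dropped
rather than reported at p = 1, so they do not inflate the multiple-testing
burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, UsageError

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "bh_fdr",
    "enrich_terms",
    "read_term_map",
    "results_to_frame",
    "DEFAULT_FDR_MAX",
]

DEFAULT_FDR_MAX = 0.001


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment: counts, hypergeometric p, and BH-adjusted FDR."""

    term: str
    k: int  # study proteins annotated with the term
    K: int  # background proteins annotated with the term
    n: int  # study size
    N: int  # background size
    p_value: float
    fdr: float


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise UsageError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in the input order.

    adjusted_(i) = min_{j >= i} ( p_(j) * m / j ), clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise UsageError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adjusted_sorted, 0.0, 1.0)
    return adjusted


def enrich_terms(
    study: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Score every term against the study set over the whole background.

    ``study`` must be a subset of ``background``; term annotations outside the
    background are ignored for counting.  One result per term with K >= 1,
    sorted by (fdr, p, term).
    """
    study_set = set(study)
    background_set = set(background)
    stray = sorted(study_set - background_set)
    if stray:
        raise UsageError(
            f"study proteins missing from background: {', '.join(stray[:10])}"
            + ("..." if len(stray) > 10 else "")
        )
    if not background_set:
        raise UsageError("background must not be empty")
    N, n = len(background_set), len(study_set)
    rows = []
    for term in sorted(terms):
        annotated = set(terms[term]) & background_set
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & study_set)
        rows.append((term, k, K))
    pvals = [hypergeom_pvalue(k, K, n, N) for _, k, K in rows]
    fdrs = bh_fdr(pvals)
    results = [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N, p_value=p, fdr=float(q))
        for (t, k, K), p, q in zip(rows, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term))
    return results


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (term, protein) TSV into a term -> protein-set map."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ],
        columns=["term", "k", "K", "n", "N", "p_value", "fdr"],
    )
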