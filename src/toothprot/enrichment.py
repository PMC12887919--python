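"""Over-representation analysis with entity-ratio ranking.

For a query of n proteins drawn from a background proteome of N
proteins, a pathway holding K background proteins of which x appear in
the query is scored with the exact hypergeometric upper tail
P(X >= x).  The *entity ratio* K/N measures how large a slice of the
organism's proteome the pathway covers; significant pathways
(p <= alpha, no multiplicity correction by default) are ranked by
entity ratio, descending.

The background N is usually not published alongside such tables; it can
be recovered from printed (K, entity ratio) pairs with
:func:`infer_background`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import PathwaySet, ValidationError

__all__ = [
    "EnrichmentResult",
    "BackgroundFit",
    "hypergeom_upper_tail",
    "randomized_tail_pvalue",
    "enrich",
    "infer_background",
    "profile_categories",
    "enrichment_to_frame",
]


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_hypergeom(x: int, K: int, n: int, N: int) -> None:
    if N < 0 or K < 0 or n < 0 or x < 0:
        raise ValidationError("hypergeometric arguments must be non-negative")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if x > min(K, n):
        raise ValidationError(f"x={x} exceeds min(K={K}, n={n})")


def _log_pmf_terms(K: int, n: int, N: int, xs: np.ndarray) -> np.ndarray:
    return (
        _log_binom(K, xs)
        + _log_binom(N - K, n - xs)
        - _log_binom(N, n)
    )


def hypergeom_upper_tail(x: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(N, K, n).

    Computed by summing probability masses in log space (log-factorial
    terms), which stays accurate for backgrounds up to 10^7 proteins.
    Returns exactly 1.0 when x = 0.
    """
    _validate_hypergeom(x, K, n, N)
    if x == 0:
        return 1.0
    hi = min(K, n)
    lo = max(x, n - (N - K))
    if lo > hi:
        return 0.0
    xs = np.arange(lo, hi + 1)
    value = float(np.exp(logsumexp(_log_pmf_terms(K, n, N, xs))))
    return min(value, 1.0)


def randomized_tail_pvalue(
    x: int, K: int, n: int, N: int, u: float
) -> float:
    """Randomized ("U-value") version of the upper-tail p.

    ``P(X > x) + u * P(X = x)`` with ``u ~ Uniform(0, 1)`` is exactly
    uniform under the null even though X is discrete, which makes it
    the correct object for distributional calibration checks of the
    hypergeometric test.  Ordinary results use
    :func:`hypergeom_upper_tail`.
    """
    _validate_hypergeom(x, K, n, N)
    tail_above = hypergeom_upper_tail(x + 1, K, n, N) if x < min(K, n) else 0.0
    pmf = float(np.exp(_log_pmf_terms(K, n, N, np.array([x]))[0]))
    return tail_above + u * pmf


@dataclass(frozen=True)
class EnrichmentResult:
    """Scored pathway: found count x, pathway size K, query size n,
    background N, entity ratio K/N, hypergeometric p and rank."""

    pathway_id: str
    name: str
    x: int
    K: int
    n: int
    N: int
    entities_ratio: float
    found_ratio: float
    p_value: float
    significant: bool
    rank: Optional[int]


def enrich(
    query: Iterable[str],
    pathways: Sequence[PathwaySet],
    N: int,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every pathway hit by the query against background size N.

    Only pathways with at least one query member are reported.
    Significant pathways (raw p <= alpha) receive ranks 1..m ordered by
    entity ratio descending, ties broken by smaller p then pathway id;
    non-significant pathways follow unranked.
    """
    query_set = set(query)
    if not query_set:
        raise ValidationError("query set is empty")
    n = len(query_set)
    if n > N:
        raise ValidationError(f"query size {n} exceeds background {N}")
    scored = []
    for pw in pathways:
        if pw.size > N:
            raise ValidationError(
                f"pathway {pw.pathway_id} size {pw.size} exceeds background {N}"
            )
        x = len(query_set & pw.members)
        if x == 0:
            continue
        p = hypergeom_upper_tail(x, pw.size, n, N)
        scored.append(
            EnrichmentResult(
                pathway_id=pw.pathway_id,
                name=pw.name,
                x=x,
                K=pw.size,
                n=n,
                N=N,
                entities_ratio=pw.size / N,
                found_ratio=x / n,
                p_value=p,
                significant=p <= alpha,
                rank=None,
            )
        )
    sig = [r for r in scored if r.significant]
    rest = [r for r in scored if not r.significant]
    sig.sort(key=lambda r: (-r.entities_ratio, r.p_value, r.pathway_id))
    rest.sort(key=lambda r: (r.p_value, r.pathway_id))
    ranked = [
        EnrichmentResult(**{**r.__dict__, "rank": i})
        for i, r in enumerate(sig, start=1)
    ]
    return ranked + rest


@dataclass(frozen=True)
class BackgroundFit:
    """Result of recovering the background proteome size N from printed
    (pathway size, entity ratio) pairs."""

    n_background: int
    residual: float
    feasible_interval: Optional[tuple[int, int]]
    per_pair_intervals: tuple[tuple[int, int], ...]
    consistent: bool


def _pair_interval(K: int, ratio: float, decimals: int = 4) -> tuple[int, int]:
    """Integer N range compatible with ``round(K/N, decimals) == ratio``."""
    half = 0.5 * 10 ** (-decimals)
    lo_ratio, hi_ratio = ratio - half, ratio + half
    n_lo = int(np.ceil(K / hi_ratio)) if hi_ratio > 0 else K
    n_hi = int(np.floor(K / lo_ratio)) if lo_ratio > 0 else 10 ** 8
    while n_lo <= n_hi and round(K / n_lo, decimals) != round(ratio, decimals):
        n_lo += 1
    while n_hi >= n_lo and round(K / n_hi, decimals) != round(ratio, decimals):
        n_hi -= 1
    return n_lo, n_hi


def infer_background(
    pairs: Sequence[tuple[int, float]], decimals: int = 4
) -> BackgroundFit:
    """Recover the integer background size N from printed (K, ratio) pairs.

    Returns the N minimizing the squared mismatch between
    ``round(K/N, decimals)`` and each printed ratio, together with the
    per-pair feasible intervals implied by rounding and their
    intersection (empty intersections are reported, not fatal).
    """
    pairs = [(K, r) for K, r in pairs if r > 0]
    if not pairs:
        raise ValidationError("need at least one (K, ratio) pair with ratio > 0")
    intervals = tuple(_pair_interval(K, r, decimals) for K, r in pairs)
    lo = max(max(i[0] for i in intervals), max(K for K, _ in pairs))
    hi = min(i[1] for i in intervals)
    consistent = lo <= hi
    search_lo = max(min(i[0] for i in intervals), max(K for K, _ in pairs))
    search_hi = max(i[1] for i in intervals)
    candidates = np.arange(search_lo, search_hi + 1)
    Ks = np.array([K for K, _ in pairs], dtype=float)
    ratios = np.array([r for _, r in pairs], dtype=float)
    rounded = np.round(Ks[None, :] / candidates[:, None], decimals)
    sse = ((rounded - ratios[None, :]) ** 2).sum(axis=1)
    best = int(np.argmin(sse))
    return BackgroundFit(
        n_background=int(candidates[best]),
        residual=float(sse[best]),
        feasible_interval=(int(lo), int(hi)) if consistent else None,
        per_pair_intervals=intervals,
        consistent=consistent,
    )


def profile_categories(
    query: Iterable[str],
    category_map: Mapping[str, Sequence[tuple[str, str]]],
) -> dict[str, dict[str, object]]:
    """Descriptive per-namespace term counts for a query set.

    ``category_map`` maps accession -> [(namespace, term), ...]; a
    protein carrying several terms counts once under each.  Query
    members absent from the map are tallied as unannotated.  Each
    namespace reports term counts and the proportion of annotated query
    members carrying the term.
    """
    query_set = set(query)
    profile: dict[str, dict[str, object]] = {}
    if not query_set:
        return profile
    unannotated = 0
    counts: dict[str, dict[str, int]] = {}
    annotated: dict[str, set[str]] = {}
    for acc in sorted(query_set):
        terms = category_map.get(acc)
        if not terms:
            unannotated += 1
            continue
        for namespace, term in terms:
            counts.setdefault(namespace, {})
            counts[namespace][term] = counts[namespace].get(term, 0) + 1
            annotated.setdefault(namespace, set()).add(acc)
    for namespace, term_counts in counts.items():
        denom = len(annotated[namespace])
        profile[namespace] = {
            "counts": dict(sorted(term_counts.items())),
            "proportions": {
                term: c / denom for term, c in sorted(term_counts.items())
            },
            "n_annotated": denom,
        }
    profile["_unannotated"] = {"count": unannotated}
    return profile


def enrichment_to_frame(results: Sequence[EnrichmentResult]):
    """DataFrame mirroring the published enrichment-table columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "name": [r.name for r in results],
            "found": [r.x for r in results],
            "pathway_size": [r.K for r in results],
            "entities_ratio": [r.entities_ratio for r in results],
            "entities_p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "rank": [r.rank for r in results],
        }
    )
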