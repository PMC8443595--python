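"""Hypergeometric over-representation statistics.

The over-representation p-value for an overlap of ``k`` genes between a
query of size ``n`` and an annotated set of size ``K`` inside a universe
of ``N`` genes is the upper tail of the hypergeometric distribution,

    P(X >= k) = sum_{x=k}^{min(n,K)} C(K,x) C(N-K,n-x) / C(N,n),

evaluated from an exact big-integer anchor term with a stable term-ratio
recurrence; tails too small for double precision fall back to log-space
summation of log-gamma binomials so interactome-scale tests never
underflow.  The enrichment ratio is the fold over-representation
(k/n)/(K/N).  One-sided Fisher's exact test ("greater") is
mathematically the same tail and is offered as an alternative mode via
scipy.

Multiple-test adjustment is Benjamini-Hochberg step-up, delegated to
statsmodels; all p-values passed in one call form one adjustment family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, List, Sequence, Set

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection

# floor applied to p-values before -log10 transforms downstream
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts for one over-representation test.

    k: overlap size, n: query size, K: annotated-set size, N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        for name in ("k", "n", "K", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"ContingencyCounts.{name} must be a non-negative integer")
        if self.n > self.N or self.K > self.N:
            raise ValueError(
                f"ContingencyCounts: need n <= N and K <= N, got "
                f"n={self.n}, K={self.K}, N={self.N}"
            )


@dataclass
class EnrichmentResult:
    """One query-vs-set test with raw and BH-adjusted significance."""

    query_label: str
    set_label: str
    counts: ContingencyCounts
    p_value: float
    enrichment_ratio: float
    overlap_genes: List[str]
    q_value: float = float("nan")


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


# exact big-integer binomials are cheap up to this universe size; beyond it
# (far outside this package's use cases) fall back to log-gamma arithmetic
_EXACT_LIMIT = 100_000


def _pmf_exact(k: int, n: int, K: int, N: int) -> float:
    num = math.comb(K, k) * math.comb(N - K, n - k)
    return float(Fraction(num, math.comb(N, n)))


def hypergeom_pmf(c: ContingencyCounts) -> float:
    """P(X = k); zero outside the support [max(0, n+K-N), min(n, K)].

    Computed with exact integer binomials (correctly rounded on conversion)
    for universes up to 1e5 genes; larger universes use log-gamma binomials.
    """
    lo = max(0, c.n + c.K - c.N)
    hi = min(c.n, c.K)
    if c.k < lo or c.k > hi:
        return 0.0
    if c.N <= _EXACT_LIMIT:
        return _pmf_exact(c.k, c.n, c.K, c.N)
    logp = (
        _log_binom(c.K, c.k)
        + _log_binom(c.N - c.K, c.n - c.k)
        - _log_binom(c.N, c.n)
    )
    return float(np.exp(logp))


def _sf_loggamma(k: int, n: int, K: int, N: int, hi: int) -> float:
    ks = np.arange(k, hi + 1)
    logs = _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(logs))))


def hypergeom_sf(c: ContingencyCounts) -> float:
    """Upper-tail p-value P(X >= k); equals 1 when k is at/below the support.

    The tail is anchored at an exactly computed P(X = k) and extended by the
    stable term-ratio recurrence with compensated summation, keeping the
    absolute error near machine precision; tails too small to anchor in
    double precision (and universes beyond 1e5) use log-space summation of
    log-gamma binomials instead.
    """
    lo = max(0, c.n + c.K - c.N)
    hi = min(c.n, c.K)
    if c.k <= lo:
        return 1.0
    if c.k > hi:
        return 0.0
    if c.N > _EXACT_LIMIT:
        return _sf_loggamma(c.k, c.n, c.K, c.N, hi)
    anchor = _pmf_exact(c.k, c.n, c.K, c.N)
    if anchor == 0.0:  # below double-precision range: log-space fallback
        return _sf_loggamma(c.k, c.n, c.K, c.N, hi)
    terms = [anchor]
    t = anchor
    for x in range(c.k, hi):
        t *= (c.K - x) * (c.n - x) / ((x + 1) * (c.N - c.K - c.n + x + 1))
        terms.append(t)
    return min(1.0, math.fsum(terms))


def enrichment_ratio(c: ContingencyCounts) -> float:
    """(k/n) / (K/N), the fold over-representation."""
    if c.n == 0 or c.K == 0:
        raise ValueError("enrichment_ratio undefined for n=0 or K=0")
    return (c.k / c.n) / (c.K / c.N)


def fisher_greater(c: ContingencyCounts) -> float:
    """One-sided Fisher's exact p for the same 2x2 table (via scipy)."""
    table = [
        [c.k, c.n - c.k],
        [c.K - c.k, c.N - c.K - c.n + c.k],
    ]
    return float(fisher_exact(table, alternative="greater")[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_test(
    query: Set[str],
    annotated: Set[str],
    universe: Set[str],
    query_label: str = "query",
    set_label: str = "set",
    mode: str = "hypergeometric",
) -> EnrichmentResult:
    """Test one query against one annotated set inside ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    q = query & universe
    a = annotated & universe
    counts = ContingencyCounts(k=len(q & a), n=len(q), K=len(a), N=len(universe))
    if mode == "hypergeometric":
        p = hypergeom_sf(counts)
    elif mode == "fisher_greater":
        p = fisher_greater(counts)
    else:
        raise ValueError(f"unknown test mode {mode!r}")
    ratio = enrichment_ratio(counts) if counts.n > 0 and counts.K > 0 else 0.0
    return EnrichmentResult(
        query_label=query_label,
        set_label=set_label,
        counts=counts,
        p_value=p,
        enrichment_ratio=ratio,
        overlap_genes=sorted(q & a),
    )


def set_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    mode: str = "hypergeometric",
    query_label: str = "query",
) -> List[EnrichmentResult]:
    """Test a query gene list against every set in a collection.

    Genes outside the universe are dropped with a warning; q-values are
    BH-adjusted across the whole collection (one family per invocation)
    and results come back sorted by raw p-value (ties by set name).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"query {query_label!r}: {len(outside)} gene(s) outside the universe dropped"
        )
    query_set &= universe_set
    if not query_set:
        raise ValueError(f"query {query_label!r} is empty after universe intersection")
    results = [
        overlap_test(
            query_set,
            set(collection.genes(name)),
            universe_set,
            query_label=query_label,
            set_label=name,
            mode=mode,
        )
        for name in collection
    ]
    qvals = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.set_label))
    return results


def write_results_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "query_label\tset_label\tk\tn\tK\tN\tenrichment_ratio\tp_value\tq_value\toverlap_genes\n"
        )
        for r in results:
            c = r.counts
            fh.write(
                f"{r.query_label}\t{r.set_label}\t{c.k}\t{c.n}\t{c.K}\t{c.N}\t"
                f"{r.enrichment_ratio:.6g}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{','.join(r.overlap_genes)}\n"
            )
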