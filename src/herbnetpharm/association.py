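"""Herb-disease literature association.

Each herb's literature profile is a 2x2 draw: of N corpus articles, K
mention the disease; of the n articles about the herb, k mention the
disease.  Under the null of no association k ~ Hypergeometric(N, K, n),
and the herb's association p-value is the upper tail P(X >= k).  Herbs
with p <= alpha (default 0.01) are selected.

The corpus here is eight-digit-sized (N ~ 1.05e8), so tail probabilities
are computed in log space with log-gamma arithmetic; naive factorials are
useless at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .core_model_io import CorpusStats, HerbLiteratureRecord

__all__ = ["AssociationResult", "hypergeom_upper_tail", "herb_association"]


@dataclass
class AssociationResult:
    herb_id: str
    p_value: float
    expected_k: float  # n * K / N under the null
    enrichment_ratio: float  # observed k over expected_k
    selected: bool


def _check_domain(N: int, K: int, n: int, k: int) -> None:
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    if not 0 <= K <= N:
        raise ValueError(f"K must satisfy 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"n must satisfy 0 <= n <= N, got n={n}, N={N}")
    if k > min(n, K):
        raise ValueError(
            f"k must satisfy k <= min(n, K); got k={k}, n={n}, K={K}"
        )


@lru_cache(maxsize=16)
def _log_sf_suffix(N: int, K: int, n: int) -> np.ndarray:
    """log P(X >= k) for k = 0 .. min(n, K), via log-gamma pmf terms.

    A suffix log-sum-exp over the full support keeps the result accurate
    deep in the tail, where the linear-space sum would underflow.
    """
    m = min(n, K)
    lo = max(0, n + K - N)
    i = np.arange(lo, m + 1)
    logc = gammaln(N - n + 1) + gammaln(n + 1) - gammaln(N + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        + logc
    )
    # suffix logsumexp via reverse logaddexp.accumulate
    suffix = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    out = np.full(m + 1, -np.inf)
    out[lo:] = suffix
    if lo > 0:
        out[:lo] = suffix[0]  # P(X >= k) = 1 for k below the support floor
    return out


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in [0, 1].

    Computed from log-gamma terms with a log-space suffix sum, so it is
    usable unchanged at corpus scale (N ~ 1e8) and at toy scale.
    """
    _check_domain(N, K, n, k)
    if k <= 0:
        return 1.0
    ls = float(_log_sf_suffix(N, K, n)[k])
    if ls == -np.inf:
        return 0.0
    # a feasible k always has strictly positive tail mass; keep it so even
    # when exp() would underflow
    p = max(float(np.exp(ls)), 5e-324)
    return min(p, 1.0)


def herb_association(
    corpus: CorpusStats,
    herbs: list[HerbLiteratureRecord],
    alpha: float = 0.01,
    adjust: str | None = None,
) -> list[AssociationResult]:
    """Upper-tail association p-value and selection flag for each herb.

    Selection mirrors a per-herb alpha rule (no multiplicity correction by
    default); pass ``adjust="bh"`` to select on Benjamini-Hochberg adjusted
    p-values instead.  Input order is preserved.
    """
    N, K = corpus.n_corpus, corpus.k_disease_corpus
    results: list[AssociationResult] = []
    pvals = []
    for h in herbs:
        p = hypergeom_upper_tail(N, K, h.n_total_articles, h.k_disease_articles)
        expected = h.n_total_articles * K / N
        ratio = h.k_disease_articles / expected if expected > 0 else float("nan")
        pvals.append(p)
        results.append(
            AssociationResult(
                herb_id=h.herb_id,
                p_value=p,
                expected_k=expected,
                enrichment_ratio=ratio,
                selected=False,
            )
        )
    if not results:
        return results
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        crit = p_adj
    elif adjust is None:
        crit = pvals
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    for r, p in zip(results, crit):
        r.selected = bool(p <= alpha)
    return results
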