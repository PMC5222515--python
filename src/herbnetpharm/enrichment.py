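"""Gene-set over-representation analysis (ORA).

For a selected set of n targets out of a universe of N genes, a term
annotating K universe genes and overlapping the selection in k is scored
with the upper-tail hypergeometric probability P(X >= k) — the same
statistic (and code) used for herb-literature association.  The EASE
variant scores P(X >= k - 1), the conservative score reported by the
DAVID service.  Benjamini-Hochberg adjusted values are reported
alongside, but retention uses the raw p <= alpha rule by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from statsmodels.stats.multitest import multipletests

from .association import hypergeom_upper_tail
from .core_model_io import GeneSetCollection, ValidationError

__all__ = ["EnrichmentResult", "ora", "top_terms"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k_overlap: int
    n_selected: int
    K_term: int
    N_universe: int
    p_raw: float
    p_adjusted: float
    rank: int = 0


def ora(
    selected: Iterable[str],
    sets: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    variant: str = "standard",
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``selected`` against every term in ``sets``.

    Each term is intersected with the universe (default: all genes in the
    collection) before testing.  Terms with raw p <= alpha are retained,
    sorted ascending by (p_raw, term_id) and ranked 1..T.  BH adjustment
    is computed across all tested terms, before retention.
    """
    if variant not in ("standard", "ease"):
        raise ValueError(f"unknown ORA variant: {variant!r}")
    selected = set(selected)
    uni = frozenset(universe) if universe is not None else sets.effective_universe()
    if not uni:
        raise ValueError("empty universe")
    stray = selected - uni
    if stray:
        raise ValidationError(
            f"selected ids outside the universe: {', '.join(sorted(stray)[:10])}"
        )
    N, n = len(uni), len(selected)
    rows: list[EnrichmentResult] = []
    for term in sorted(sets.sets):
        members = sets.sets[term] & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        k_eff = max(k - 1, 0) if variant == "ease" else k
        p = hypergeom_upper_tail(N, K, n, k_eff)
        rows.append(
            EnrichmentResult(
                term_id=term,
                term_name=sets.names.get(term, term),
                k_overlap=k,
                n_selected=n,
                K_term=K,
                N_universe=N,
                p_raw=p,
                p_adjusted=1.0,
            )
        )
    if not rows:
        return []
    _, p_adj, _, _ = multipletests([r.p_raw for r in rows], method="fdr_bh")
    for r, q in zip(rows, p_adj):
        r.p_adjusted = float(q)
    kept = [r for r in rows if r.p_raw <= alpha]
    kept.sort(key=lambda r: (r.p_raw, r.term_id))
    for i, r in enumerate(kept, start=1):
        r.rank = i
    return kept


def top_terms(
    results: list[EnrichmentResult], limit: int = 20
) -> list[EnrichmentResult]:
    """First ``limit`` results by ascending (p_raw, term_id)."""
    if limit < 0:
        raise ValueError(f"limit must be non-negative, got {limit}")
    return sorted(results, key=lambda r: (r.p_raw, r.term_id))[:limit]
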