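"""Consensus acceptance of predicted compound-target interactions.

Each (compound, target) pair carries two confidence scores from
independent chemogenomic predictors (a random forest and an SVM).  A pair
is accepted only when both scores clear their thresholds strictly
(rf > 0.8 and svm > 0.7 by default) and, when a curated whitelist of
disease-relevant targets is supplied, the target is on it.

The predictors themselves are pretrained upstream models and are not part
of this package; a deterministic surrogate scorer with planted structure
makes the downstream network stages testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core_model_io import (
    CompoundRecord,
    ConfigurationError,
    InteractionScore,
    TargetRecord,
)

__all__ = ["ConsensusConfig", "consensus_filter", "surrogate_scores"]


@dataclass(frozen=True)
class ConsensusConfig:
    rf_min: float = 0.8
    svm_min: float = 0.7
    target_whitelist: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for name in ("rf_min", "svm_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.target_whitelist is not None:
            object.__setattr__(
                self, "target_whitelist", frozenset(self.target_whitelist)
            )


def consensus_filter(
    scores: Iterable[InteractionScore], cfg: ConsensusConfig = ConsensusConfig()
) -> list[InteractionScore]:
    """Keep pairs with rf > rf_min AND svm > svm_min (strict), in order.

    Thresholds are exclusive: a score exactly at the threshold is
    rejected.  With a whitelist, the target must additionally be listed.
    Returned records have ``accepted=True``; input order is preserved.
    """
    out: list[InteractionScore] = []
    for s in scores:
        ok = s.rf_score > cfg.rf_min and s.svm_score > cfg.svm_min
        if ok and cfg.target_whitelist is not None:
            ok = s.target_id in cfg.target_whitelist
        if ok:
            out.append(
                InteractionScore(
                    compound_id=s.compound_id,
                    target_id=s.target_id,
                    rf_score=s.rf_score,
                    svm_score=s.svm_score,
                    accepted=True,
                )
            )
    return out


def surrogate_scores(
    compounds: Sequence[CompoundRecord],
    targets: Sequence[TargetRecord],
    planted: dict[str, float],
    seed: int,
    edge_strength: float = 1.0,
    decoys_per_compound: int = 2,
) -> list[InteractionScore]:
    """Deterministic surrogate for the pretrained interaction predictors.

    ``planted`` maps each herb id to the mean number of accepted targets
    per compound in that herb.  For each compound, a Poisson-distributed
    number of distinct targets receives supra-threshold scores (with
    probability ``edge_strength`` per planted pair); a few decoy pairs
    per compound get sub-threshold scores so the consensus filter has
    something to reject.  Output is a pure function of the arguments.
    """
    from .synthetic_data import _interaction_scores_impl

    known = {c.herb_id for c in compounds}
    unknown = known - set(planted)
    if unknown:
        raise ConfigurationError(
            f"no planted tier for herb(s): {', '.join(sorted(unknown))}"
        )
    if not 0.0 <= edge_strength <= 1.0:
        raise ConfigurationError("edge_strength must be in [0, 1]")
    return _interaction_scores_impl(
        compounds, targets, planted, seed, edge_strength, decoys_per_compound
    )
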