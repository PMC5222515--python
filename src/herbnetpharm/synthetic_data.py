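"""Seeded generators for pipeline-shaped synthetic data.

Every stage of the analysis can be exercised without external downloads:
the generators emit compound tables, interaction scores, literature
counts and gene-set collections with the statistical structure the
pipeline assumes — descriptor distributions matching the published group
summaries, OB/DL values spanning the filter thresholds, a planted
high-degree "monarch" herb with tiered lower-degree herbs, and gene sets
with a planted enriched term.

All generators are pure functions of (config, seed): a single root seed
drives per-generator streams derived by fixed offsets, so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_model_io import (
    CompoundRecord,
    ConfigurationError,
    CorpusStats,
    DESCRIPTOR_NAMES,
    DescriptorVector,
    GeneSetCollection,
    HerbLiteratureRecord,
    InteractionScore,
    TargetRecord,
    write_compound_table,
    write_gene_sets,
    write_interaction_table,
)

__all__ = ["SimConfig", "gen_compound_table", "gen_interaction_scores",
           "gen_corpus_counts", "gen_gene_sets", "simulate",
           "PLANTED_TERM_ID"]

# Fixed stream offsets so per-module draws stay independent of one another.
_STREAM_COMPOUNDS = 1
_STREAM_INTERACTIONS = 2
_STREAM_CORPUS = 3
_STREAM_GENESETS = 4
_STREAM_REFERENCE = 5

PLANTED_TERM_ID = "PLANTED_TERM"

#: (mean, sd) per descriptor for the herbal-compound group.
HERBAL_DESCRIPTOR_PARAMS = {
    "mw": (344.15, 113.89),
    "ncic": (3.52, 1.37),
    "rbn": (2.86, 2.67),
    "nhdon": (2.57, 2.47),
    "nhacc": (5.63, 3.50),
    "hy": (0.83, 1.80),
    "tpsa": (90.15, 57.95),
    "mlogp": (1.87, 2.08),
}

#: (mean, sd) per descriptor for the reference approved-drug group.
REFERENCE_DESCRIPTOR_PARAMS = {
    "mw": (346.57, 208.89),
    "ncic": (2.46, 1.72),
    "rbn": (5.58, 5.88),
    "nhdon": (3.17, 3.50),
    "nhacc": (6.46, 5.59),
    "hy": (1.47, 2.76),
    "tpsa": (99.93, 90.43),
    "mlogp": (1.33, 2.50),
}

_COUNT_DESCRIPTORS = ("ncic", "nhdon", "nhacc", "rbn")
_NONNEG_DESCRIPTORS = ("mw", "tpsa")


@dataclass
class SimConfig:
    """Default scenario mirrors the study's scale: 20 herbs, 1618 raw
    ingredients of which ~9.3% pass the joint screen, 33 targets, a
    1 / 7 / 12 herb-degree tiering, and 3 pathway-sized gene sets plus
    17 decoys."""

    n_herbs: int = 20
    n_compounds: int = 1618
    compounds_per_herb: Optional[tuple[int, int]] = None  # overrides n_compounds
    descriptor_params: dict = field(
        default_factory=lambda: dict(HERBAL_DESCRIPTOR_PARAMS)
    )
    pass_fraction: float = 150 / 1618  # expected joint OB/DL pass rate
    ob_threshold: float = 30.0
    dl_threshold: float = 0.18
    # (herb count, mean accepted targets per compound) per degree tier
    tiers: tuple[tuple[int, float], ...] = ((1, 12.0), (7, 7.24), (12, 6.74))
    # relative ingredient share per herb in each tier: the monarch herb
    # contributes far more candidates than any minister or assistant herb
    tier_compound_weights: tuple[float, ...] = (32.0, 41 / 7, 57 / 12)
    edge_strength: float = 1.0
    decoys_per_compound: int = 2
    n_targets: int = 33
    n_background_genes: int = 300  # decoy genes padding the ORA universe
    n_gene_sets: int = 20
    set_size_range: tuple[int, int] = (5, 24)
    planted_fraction: float = 1.0
    corpus_n: int = 104544921
    corpus_k: int = 791592
    articles_per_herb: int = 50000
    enrichment_factors: tuple[float, ...] | float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_herbs <= 0 or self.n_targets <= 0:
            raise ConfigurationError("n_herbs and n_targets must be positive")
        if sum(c for c, _ in self.tiers) != self.n_herbs:
            raise ConfigurationError(
                f"tier herb counts {[c for c, _ in self.tiers]} must sum to "
                f"n_herbs={self.n_herbs}"
            )
        if any(m < 0 for _, m in self.tiers):
            raise ConfigurationError("tier means must be non-negative")
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ConfigurationError("pass_fraction must be in [0, 1]")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigurationError("planted_fraction must be in [0, 1]")

    def herb_ids(self) -> list[str]:
        return [f"herb_{i + 1:02d}" for i in range(self.n_herbs)]

    def target_ids(self) -> list[str]:
        return [f"T{i + 1:03d}" for i in range(self.n_targets)]

    def background_gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_background_genes)]

    def designated_selected(self) -> list[str]:
        """The target subset the planted enriched term is built over."""
        ids = self.target_ids()
        return ids[: max(1, len(ids) // 3)]

    def herb_weights(self) -> dict[str, float]:
        """Relative ingredient share per herb (tier-wise weights)."""
        if len(self.tier_compound_weights) != len(self.tiers):
            raise ConfigurationError(
                "tier_compound_weights must match the number of tiers"
            )
        weights: dict[str, float] = {}
        herbs = iter(self.herb_ids())
        for (count, _), w in zip(self.tiers, self.tier_compound_weights):
            for _ in range(count):
                weights[next(herbs)] = w
        return weights

    def tier_means(self) -> dict[str, float]:
        """herb_id -> planted mean accepted targets per compound."""
        means: dict[str, float] = {}
        herbs = iter(self.herb_ids())
        for count, mean in self.tiers:
            for _ in range(count):
                means[next(herbs)] = mean
        return means


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg_seed])


def _draw_descriptor(rng, name: str, mean: float, sd: float, size: int):
    x = rng.normal(mean, sd, size=size)
    if name in _COUNT_DESCRIPTORS:
        return np.clip(np.rint(x), 0, None)
    if name in _NONNEG_DESCRIPTORS:
        # truncate at a small positive floor (mw must stay positive)
        floor = 1.0 if name == "mw" else 0.0
        bad = x <= floor if name == "mw" else x < floor
        while bad.any():
            x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = x <= floor if name == "mw" else x < floor
        return x
    return x


def gen_compound_table(cfg: SimConfig) -> list[CompoundRecord]:
    """Synthetic ingredient table with descriptors and OB/DL values.

    OB/DL are drawn as a mixture: with probability ``pass_fraction`` both
    clear their thresholds; otherwise at least one falls below, the
    failure mode chosen uniformly among ob-only / dl-only / both.
    """
    rng = _rng(cfg.seed, _STREAM_COMPOUNDS)
    herbs = cfg.herb_ids()
    if cfg.compounds_per_herb is not None:
        lo, hi = cfg.compounds_per_herb
        counts = rng.integers(lo, hi + 1, size=cfg.n_herbs)
    else:
        # largest-remainder allocation of n_compounds by tier weight
        w = np.array([cfg.herb_weights()[h] for h in herbs], dtype=float)
        exact = cfg.n_compounds * w / w.sum()
        counts = np.floor(exact).astype(int)
        short = cfg.n_compounds - int(counts.sum())
        for i in np.argsort(-(exact - counts))[:short]:
            counts[i] += 1
    total = int(counts.sum())
    desc_cols = {}
    for name in DESCRIPTOR_NAMES:
        mean, sd = cfg.descriptor_params[name]
        desc_cols[name] = _draw_descriptor(rng, name, mean, sd, total)
    passes = rng.random(total) < cfg.pass_fraction
    ob = np.empty(total)
    dl = np.empty(total)
    mode = rng.integers(0, 3, size=total)  # 0 fail ob, 1 fail dl, 2 fail both
    for i in range(total):
        if passes[i]:
            ob[i] = rng.uniform(cfg.ob_threshold, 110.0)
            dl[i] = rng.uniform(cfg.dl_threshold, 0.95)
        else:
            ob_fail = mode[i] in (0, 2)
            dl_fail = mode[i] in (1, 2)
            ob[i] = (rng.uniform(0.0, cfg.ob_threshold * 0.999) if ob_fail
                     else rng.uniform(cfg.ob_threshold, 110.0))
            dl[i] = (rng.uniform(0.0, cfg.dl_threshold * 0.999) if dl_fail
                     else rng.uniform(cfg.dl_threshold, 0.95))
    records: list[CompoundRecord] = []
    idx = 0
    for h, c in zip(herbs, counts):
        for _ in range(int(c)):
            records.append(
                CompoundRecord(
                    compound_id=f"C{idx + 1:04d}",
                    name=f"compound_{idx + 1:04d}",
                    herb_id=h,
                    ob=float(np.round(ob[idx], 2)),
                    dl=float(np.round(dl[idx], 3)),
                    descriptors=DescriptorVector.from_mapping(
                        {n: desc_cols[n][idx] for n in DESCRIPTOR_NAMES}
                    ),
                )
            )
            idx += 1
    return records


def gen_reference_descriptors(cfg: SimConfig, n_drugs: int = 200) -> np.ndarray:
    """Synthetic reference-drug descriptor matrix (rows follow
    DESCRIPTOR_NAMES order) drawn from the approved-drug group summary."""
    rng = _rng(cfg.seed, _STREAM_REFERENCE)
    cols = []
    for name in DESCRIPTOR_NAMES:
        mean, sd = REFERENCE_DESCRIPTOR_PARAMS[name]
        cols.append(_draw_descriptor(rng, name, mean, sd, n_drugs))
    return np.column_stack(cols)


def _interaction_scores_impl(
    compounds: Sequence[CompoundRecord],
    targets: Sequence[TargetRecord] | Sequence[str],
    herb_means: dict[str, float],
    seed: int,
    edge_strength: float,
    decoys_per_compound: int,
) -> list[InteractionScore]:
    """Shared worker behind the surrogate scorer and the generator."""
    rng = np.random.default_rng([_STREAM_INTERACTIONS, seed])
    target_ids = [t.target_id if isinstance(t, TargetRecord) else str(t)
                  for t in targets]
    n_t = len(target_ids)
    out: list[InteractionScore] = []
    for comp in compounds:
        mean = herb_means[comp.herb_id]
        d = min(int(rng.poisson(mean)), n_t)
        chosen = rng.choice(n_t, size=d, replace=False) if d else []
        chosen_set = set(int(j) for j in chosen)
        for j in chosen_set:
            if rng.random() < edge_strength:
                rf = rng.uniform(0.801, 0.999)
                svm = rng.uniform(0.701, 0.999)
            else:
                rf = rng.uniform(0.0, 0.799)
                svm = rng.uniform(0.0, 0.699)
            out.append(InteractionScore(comp.compound_id, target_ids[j],
                                        float(rf), float(svm)))
        n_decoy = min(decoys_per_compound, n_t - len(chosen_set))
        if n_decoy > 0:
            pool = [j for j in range(n_t) if j not in chosen_set]
            decoys = rng.choice(len(pool), size=n_decoy, replace=False)
            for jj in decoys:
                j = pool[int(jj)]
                out.append(
                    InteractionScore(
                        comp.compound_id,
                        target_ids[j],
                        float(rng.uniform(0.0, 0.799)),
                        float(rng.uniform(0.0, 0.999)),
                    )
                )
    return out


def gen_interaction_scores(
    cfg: SimConfig,
    compounds: Sequence[CompoundRecord],
    targets: Sequence[TargetRecord] | Sequence[str],
) -> list[InteractionScore]:
    """Sparse RF/SVM score table with planted herb-degree tiers.

    Each compound receives Poisson(tier mean) supra-threshold target
    pairs (probability ``edge_strength`` each) plus a few sub-threshold
    decoy pairs.  Deterministic for a fixed config seed.
    """
    means = cfg.tier_means()
    unknown = {c.herb_id for c in compounds} - set(means)
    if unknown:
        raise ConfigurationError(
            f"compounds reference herbs outside the tier spec: "
            f"{', '.join(sorted(unknown))}"
        )
    return _interaction_scores_impl(
        compounds, targets, means, cfg.seed, cfg.edge_strength,
        cfg.decoys_per_compound,
    )


def gen_corpus_counts(
    cfg: SimConfig,
) -> tuple[CorpusStats, list[HerbLiteratureRecord]]:
    """Per-herb literature counts under configurable enrichment.

    Herb k counts are Binomial(n, factor * K / N); factor 1 is a null
    (unassociated) herb, factor 0 yields k = 0.
    """
    rng = _rng(cfg.seed, _STREAM_CORPUS)
    corpus = CorpusStats(n_corpus=cfg.corpus_n, k_disease_corpus=cfg.corpus_k)
    factors = cfg.enrichment_factors
    if isinstance(factors, (int, float)):
        factors = tuple([float(factors)] * cfg.n_herbs)
    if len(factors) != cfg.n_herbs:
        raise ConfigurationError(
            f"need {cfg.n_herbs} enrichment factors, got {len(factors)}"
        )
    base = cfg.corpus_k / cfg.corpus_n
    records = []
    for herb, f in zip(cfg.herb_ids(), factors):
        if f < 0:
            raise ConfigurationError(f"negative enrichment factor for {herb}")
        rate = f * base
        if rate > 1.0:
            raise ConfigurationError(
                f"{herb}: enrichment factor {f} gives rate {rate:.3g} > 1"
            )
        k = int(rng.binomial(cfg.articles_per_herb, rate))
        records.append(
            HerbLiteratureRecord(
                herb_id=herb,
                n_total_articles=cfg.articles_per_herb,
                k_disease_articles=min(k, cfg.articles_per_herb),
            )
        )
    return corpus, records


def gen_gene_sets(
    cfg: SimConfig,
    targets: Sequence[TargetRecord] | Sequence[str],
    selected: Optional[Sequence[str]] = None,
) -> GeneSetCollection:
    """Random gene sets plus one planted enriched term.

    Sets are drawn from a pool of the supplied targets padded with
    ``n_background_genes`` decoy genes, so the ORA universe is larger
    than any realistic selection.  The planted term (id ``PLANTED_TERM``)
    covers ``planted_fraction`` of the designated selected subset
    (default: the first third of the target list), so enrichment on a
    selection containing that subset recovers it at rank 1 when the
    fraction is high.  The remaining sets are uniform draws.
    """
    rng = _rng(cfg.seed, _STREAM_GENESETS)
    ids = [t.target_id if isinstance(t, TargetRecord) else str(t)
           for t in targets]
    if selected is None:
        selected = ids[: max(1, len(ids) // 3)]
    selected = list(selected)
    ids = ids + cfg.background_gene_ids()
    lo, hi = cfg.set_size_range
    if hi > len(ids):
        raise ConfigurationError(
            f"set sizes up to {hi} exceed the {len(ids)}-gene pool"
        )
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    if cfg.n_gene_sets > 0:
        n_plant = int(round(cfg.planted_fraction * len(selected)))
        if n_plant > 0:
            members = rng.choice(len(selected), size=n_plant, replace=False)
            sets[PLANTED_TERM_ID] = frozenset(selected[int(i)] for i in members)
            names[PLANTED_TERM_ID] = "planted enriched term"
        for s in range(cfg.n_gene_sets - (1 if n_plant > 0 else 0)):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(len(ids), size=size, replace=False)
            term = f"SET{s + 1:03d}"
            sets[term] = frozenset(ids[int(i)] for i in members)
            names[term] = f"random set {s + 1}"
    return GeneSetCollection(sets=sets, names=names)


def simulate(cfg: SimConfig, outdir) -> dict:
    """Run every generator and write the pipeline's input files.

    Emits compounds.tsv, interactions.tsv, herb_literature.tsv,
    gene_sets.gmt and a manifest.json recording the config and seed.
    Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds = gen_compound_table(cfg)
    targets = cfg.target_ids()
    scores = gen_interaction_scores(cfg, compounds, targets)
    corpus, herbs = gen_corpus_counts(cfg)
    sets = gen_gene_sets(cfg, targets)
    write_compound_table(compounds, outdir / "compounds.tsv")
    write_interaction_table(scores, outdir / "interactions.tsv")
    with open(outdir / "herb_literature.tsv", "w", encoding="utf-8") as fh:
        fh.write("herb_id\tn_total_articles\tk_disease_articles\n")
        for h in herbs:
            fh.write(f"{h.herb_id}\t{h.n_total_articles}\t{h.k_disease_articles}\n")
    write_gene_sets(sets, outdir / "gene_sets.gmt")
    with open(outdir / "targets.tsv", "w", encoding="utf-8") as fh:
        fh.write("target_id\tprotein_name\tuniprot_id\n")
        for i, t in enumerate(targets):
            fh.write(f"{t}\tsynthetic protein {i + 1}\tQ{i + 1:05d}\n")
    manifest = {
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "counts": {
            "compounds": len(compounds),
            "interactions": len(scores),
            "herbs": len(herbs),
            "gene_sets": len(sets),
            "targets": len(targets),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
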