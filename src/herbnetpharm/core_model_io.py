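"""Domain types and tabular/graph I/O for the herb screening pipeline.

The pipeline moves between a handful of plain-text formats: delimited
compound/herb/target tables, GMT gene-set files, and SIF/GraphML network
exports that open directly in Cytoscape.  Everything here is deliberately
dumb plumbing — validation is strict and error messages carry row or line
numbers, but no science happens in this module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ParseError",
    "DescriptorVector",
    "DESCRIPTOR_NAMES",
    "CompoundRecord",
    "HerbLiteratureRecord",
    "CorpusStats",
    "TargetRecord",
    "InteractionScore",
    "GeneSetCollection",
    "BipartiteNetwork",
    "read_compound_table",
    "read_herb_table",
    "read_target_table",
    "read_interaction_table",
    "read_gene_sets",
    "write_gene_sets",
    "write_network",
    "read_network",
    "load_herb_compounds",
    "load_herb_literature",
    "load_disease_targets",
    "load_reference_drugs",
    "PREFIX_TO_HERB",
]


class ConfigurationError(ValueError):
    """A config or file schema problem (missing column, unknown option)."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a domain invariant."""


class ParseError(ValueError):
    """A malformed line or cell; the message carries its location."""


# Corpus-wide literature constants: total articles indexed across PubMed
# and CNKI and the number of those mentioning the disease of interest.
DEFAULT_CORPUS_N = 104544921
DEFAULT_CORPUS_K = 791592

#: Canonical descriptor order used everywhere a vector is materialised.
DESCRIPTOR_NAMES = ("mw", "ncic", "nhdon", "nhacc", "rbn", "hy", "tpsa", "mlogp")

#: Compound-code prefix -> herb identifier for the packaged ingredient table.
PREFIX_TO_HERB = {
    "AY": "folium_artemisiae_argyi",
    "BJ": "dysosmae_verspiellis_rhixoma_et_radix",
    "BZ": "atractylodes_macrocephala_koidz",
    "BM": "mylabris",
    "DS": "radix_salviae",
    "WZ": "curcumae_rhizoma",
    "FJ": "stephaniae_tetrandrae_radix",
    "JH": "curcumae_longae_rhizoma",
    "MD": "cortex_moutan",
    "MT": "caulis_akebiae",
    "PP": "eriobotryae_folium",
    "SC": "pseudobulbus_cremastrae_seu_pleiones",
    "SZ": "crataegi_folium",
    "SY": "cornus_officinalis_sieb_et_zucc",
    "TD": "asparagi_radix",
    "TK": "semiaquilegiae_radix",
    "YC": "artemisiae_scopariae_herba",
    "ZJ": "gleditsiae_spina",
    "BH": "hedyotis_diffusa",
    "BL": "ampelopsis_japonica_thunb_makino",
}


@dataclass(frozen=True)
class DescriptorVector:
    """The eight physicochemical descriptors used throughout.

    mw: molecular weight (Da); ncic: ring count; nhdon/nhacc: H-bond
    donors/acceptors; rbn: rotatable bonds; hy: hydrophilic factor;
    tpsa: topological polar surface area (A^2); mlogp: Moriguchi logP.
    """

    mw: float
    ncic: float
    nhdon: float
    nhacc: float
    rbn: float
    hy: float
    tpsa: float
    mlogp: float

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValidationError(f"mw must be positive, got {self.mw}")
        if self.tpsa < 0:
            raise ValidationError(f"tpsa must be >= 0, got {self.tpsa}")
        for name in ("ncic", "nhdon", "nhacc", "rbn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(
                    f"{name} must be a non-negative integer, got {v}"
                )

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "DescriptorVector":
        return cls(**{n: float(m[n]) for n in DESCRIPTOR_NAMES})


@dataclass
class CompoundRecord:
    """One herbal ingredient with its screening-relevant annotations."""

    compound_id: str
    name: str
    herb_id: str
    ob: float  # oral bioavailability, printed percentage scale (36.91 = 36.91%)
    dl: float  # drug-likeness, Tanimoto fraction in [0, 1]
    smiles: Optional[str] = None
    descriptors: Optional[DescriptorVector] = None
    rescued: bool = False
    is_aglycone_derivative: bool = False

    def __post_init__(self) -> None:
        if self.ob < 0:
            raise ValidationError(
                f"{self.compound_id}: ob must be >= 0, got {self.ob}"
            )
        if not 0.0 <= self.dl <= 1.0:
            raise ValidationError(
                f"{self.compound_id}: dl must be in [0, 1], got {self.dl}"
            )


@dataclass
class HerbLiteratureRecord:
    """Per-herb literature counts: n articles total, k disease-relevant."""

    herb_id: str
    n_total_articles: int
    k_disease_articles: int

    def __post_init__(self) -> None:
        if self.k_disease_articles > self.n_total_articles:
            raise ValidationError(
                f"{self.herb_id}: k ({self.k_disease_articles}) exceeds "
                f"n ({self.n_total_articles})"
            )
        if min(self.n_total_articles, self.k_disease_articles) < 0:
            raise ValidationError(f"{self.herb_id}: counts must be non-negative")


@dataclass(frozen=True)
class CorpusStats:
    """Corpus-wide totals: N articles overall, K disease-relevant."""

    n_corpus: int = DEFAULT_CORPUS_N
    k_disease_corpus: int = DEFAULT_CORPUS_K

    def __post_init__(self) -> None:
        if self.n_corpus <= 0 or self.k_disease_corpus <= 0:
            raise ValidationError("corpus counts must be positive")
        if self.k_disease_corpus > self.n_corpus:
            raise ValidationError("K must not exceed N")


@dataclass(frozen=True)
class TargetRecord:
    target_id: str  # gene symbol
    protein_name: str
    uniprot_id: str


@dataclass
class InteractionScore:
    """A (compound, target) pair scored by two independent predictors."""

    compound_id: str
    target_id: str
    rf_score: float
    svm_score: float
    accepted: bool = False

    def __post_init__(self) -> None:
        for name in ("rf_score", "svm_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"({self.compound_id}, {self.target_id}): {name} must be "
                    f"in [0, 1], got {v}"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or ontology terms) over gene identifiers."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not term:
                raise ValidationError("empty term identifier")
            if any(not m for m in members):
                raise ValidationError(f"{term}: empty member identifier")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def effective_universe(self) -> frozenset[str]:
        return self.universe if self.universe is not None else self.all_genes()


@dataclass
class BipartiteNetwork:
    """A typed two-part graph (compound-target or target-pathway).

    ``edges`` are (left, right) pairs; ``node_meta`` carries per-node
    attributes such as the herb a compound belongs to.
    """

    left_kind: str
    right_kind: str
    left_nodes: set[str] = field(default_factory=set)
    right_nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    node_meta: dict[str, dict] = field(default_factory=dict)
    relation: str = "interacts"

    def validate(self) -> None:
        overlap = self.left_nodes & self.right_nodes
        if overlap:
            raise ValidationError(f"nodes in both parts: {sorted(overlap)[:5]}")
        for u, v in self.edges:
            if u not in self.left_nodes or v not in self.right_nodes:
                raise ValidationError(f"edge ({u}, {v}) has undeclared endpoint")

    def degree(self, node_id: str) -> int:
        if node_id in self.left_nodes:
            return sum(1 for u, _ in self.edges if u == node_id)
        if node_id in self.right_nodes:
            return sum(1 for _, v in self.edges if v == node_id)
        raise KeyError(f"unknown node: {node_id}")

    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self.left_nodes | self.right_nodes}
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in sorted(self.left_nodes):
            g.add_node(n, kind=self.left_kind, bipartite=0,
                       **self.node_meta.get(n, {}))
        for n in sorted(self.right_nodes):
            g.add_node(n, kind=self.right_kind, bipartite=1,
                       **self.node_meta.get(n, {}))
        g.add_edges_from(sorted(self.edges))
        return g


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f", ""}


def _parse_bool(cell: str, where: str) -> bool:
    s = str(cell).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS or s == "nan":
        return False
    raise ParseError(f"{where}: cannot interpret {cell!r} as a boolean")


def _read_table(path, required: Sequence[str], sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def _float_cell(df_cell: str, row: int, col: str, errors: list[str]):
    s = str(df_cell).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        errors.append(f"row {row}: column {col!r}: malformed numeric {df_cell!r}")
        return None


def read_compound_table(path, sep: str = "\t") -> list[CompoundRecord]:
    """Read a compound table (TSV by default) into validated records.

    Required columns: compound_id, name, herb_id, ob, dl.  Optional:
    smiles, rescued, and the eight descriptor columns.  Malformed numeric
    cells are reported together with their (1-based, data) row numbers.
    """
    df = _read_table(path, ["compound_id", "name", "herb_id", "ob", "dl"], sep)
    errors: list[str] = []
    has_desc = all(c in df.columns for c in DESCRIPTOR_NAMES)
    records: list[CompoundRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        ob = _float_cell(row["ob"], i, "ob", errors)
        dl = _float_cell(row["dl"], i, "dl", errors)
        if ob is None or dl is None:
            if str(row["ob"]).strip() == "":
                errors.append(f"row {i}: column 'ob' is empty")
            if str(row["dl"]).strip() == "":
                errors.append(f"row {i}: column 'dl' is empty")
            continue
        desc = None
        if has_desc:
            vals = {c: _float_cell(row[c], i, c, errors) for c in DESCRIPTOR_NAMES}
            if all(v is not None for v in vals.values()):
                desc = DescriptorVector.from_mapping(vals)
        smiles = str(row.get("smiles", "")).strip() or None
        rescued = _parse_bool(row.get("rescued", ""), f"row {i}")
        try:
            records.append(
                CompoundRecord(
                    compound_id=str(row["compound_id"]).strip(),
                    name=str(row["name"]).strip(),
                    herb_id=str(row["herb_id"]).strip(),
                    ob=ob,
                    dl=dl,
                    smiles=smiles,
                    descriptors=desc,
                    rescued=rescued,
                )
            )
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    seen: dict[str, int] = {}
    dups = []
    for r in records:
        seen[r.compound_id] = seen.get(r.compound_id, 0) + 1
    dups = sorted(cid for cid, c in seen.items() if c > 1)
    if dups:
        raise ValidationError(f"{path}: duplicate compound_id(s): {', '.join(dups)}")
    return records


def read_herb_table(path, sep: str = "\t") -> list[HerbLiteratureRecord]:
    df = _read_table(path, ["herb_id", "n_total_articles", "k_disease_articles"], sep)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            out.append(
                HerbLiteratureRecord(
                    herb_id=str(row["herb_id"]).strip(),
                    n_total_articles=int(row["n_total_articles"]),
                    k_disease_articles=int(row["k_disease_articles"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return out


def read_target_table(path, sep: str = "\t") -> list[TargetRecord]:
    df = _read_table(path, ["target_id", "protein_name", "uniprot_id"], sep)
    records = [
        TargetRecord(
            target_id=str(r.target_id).strip(),
            protein_name=str(r.protein_name).strip(),
            uniprot_id=str(r.uniprot_id).strip(),
        )
        for r in df.itertuples(index=False)
    ]
    seen: dict[str, int] = {}
    for r in records:
        seen[r.target_id] = seen.get(r.target_id, 0) + 1
    dups = sorted(t for t, c in seen.items() if c > 1)
    if dups:
        raise ValidationError(f"{path}: duplicate target_id(s): {', '.join(dups)}")
    return records


def read_interaction_table(path, sep: str = "\t") -> list[InteractionScore]:
    df = _read_table(path, ["compound_id", "target_id", "rf_score", "svm_score"], sep)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                InteractionScore(
                    compound_id=str(row.compound_id).strip(),
                    target_id=str(row.target_id).strip(),
                    rf_score=float(row.rf_score),
                    svm_score=float(row.svm_score),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return out


def write_compound_table(records: Iterable[CompoundRecord], path, sep: str = "\t") -> None:
    rows = []
    for r in records:
        row = {
            "compound_id": r.compound_id,
            "name": r.name,
            "herb_id": r.herb_id,
            "smiles": r.smiles or "",
            "ob": r.ob,
            "dl": r.dl,
            "rescued": str(r.rescued).lower(),
        }
        if r.descriptors is not None:
            for n in DESCRIPTOR_NAMES:
                row[n] = getattr(r.descriptors, n)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_interaction_table(scores: Iterable[InteractionScore], path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "compound_id": s.compound_id,
                "target_id": s.target_id,
                "rf_score": s.rf_score,
                "svm_score": s.svm_score,
            }
            for s in scores
        ]
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: term_id <tab> description <tab> member [member ...]."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise ParseError(f"{path}: line {lineno}: no members")
            sets[term] = frozenset(members)
            names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(coll.sets):
            members = "\t".join(sorted(coll.sets[term]))
            fh.write(f"{term}\t{coll.names.get(term, term)}\t{members}\n")


# ---------------------------------------------------------------------------
# Network export/import (SIF and GraphML, both Cytoscape-friendly)
# ---------------------------------------------------------------------------

def write_network(net: BipartiteNetwork, path, format: str = "sif") -> None:
    """Write a bipartite network.

    SIF carries ``left <tab> relation <tab> right`` edge lines (isolated
    nodes are written as bare single-field lines); GraphML additionally
    preserves node kinds and metadata, so it round-trips completely.
    """
    net.validate()
    if format == "sif":
        connected = {u for u, _ in net.edges} | {v for _, v in net.edges}
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(net.edges):
                fh.write(f"{u}\t{net.relation}\t{v}\n")
            for n in sorted((net.left_nodes | net.right_nodes) - connected):
                fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ConfigurationError(f"unknown network format: {format!r}")


def read_network(path, format: str = "graphml",
                 left_kind: str = "compound",
                 right_kind: str = "target") -> BipartiteNetwork:
    """Read a network written by :func:`write_network`.

    GraphML restores parts and metadata from node attributes.  SIF restores
    the edge set only (first column is the left part); isolated nodes in a
    SIF file are assigned to the left part by convention.
    """
    if format == "graphml":
        g = nx.read_graphml(path)
        kinds = {d.get("kind") for _, d in g.nodes(data=True)}
        kinds.discard(None)
        net = BipartiteNetwork(left_kind=left_kind, right_kind=right_kind)
        for n, d in g.nodes(data=True):
            kind = d.get("kind", left_kind)
            if d.get("bipartite", 0 if kind == left_kind else 1) == 0:
                net.left_nodes.add(n)
            else:
                net.right_nodes.add(n)
            meta = {k: v for k, v in d.items() if k not in ("kind", "bipartite")}
            if meta:
                net.node_meta[n] = meta
            if kind == left_kind:
                net.left_kind = kind
            else:
                net.right_kind = kind
        for u, v in g.edges():
            if u in net.left_nodes:
                net.edges.add((u, v))
            else:
                net.edges.add((v, u))
        net.validate()
        return net
    if format == "sif":
        net = BipartiteNetwork(left_kind=left_kind, right_kind=right_kind)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    net.left_nodes.add(fields[0])
                elif len(fields) == 3:
                    u, rel, v = fields
                    net.relation = rel
                    net.left_nodes.add(u)
                    net.right_nodes.add(v)
                    net.edges.add((u, v))
                else:
                    raise ParseError(f"{path}: line {lineno}: bad SIF line")
        net.validate()
        return net
    raise ConfigurationError(f"unknown network format: {format!r}")


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed printed tables + synthetic reference set)
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("herbnetpharm").joinpath("data", name))


def load_herb_compounds() -> list[CompoundRecord]:
    """The packaged 150-ingredient screening table for the 20 herbs."""
    return read_compound_table(_data_path("herb_compounds.tsv"))


def load_herb_literature() -> list[HerbLiteratureRecord]:
    """Per-herb literature counts for the 20 herbs."""
    return read_herb_table(_data_path("herb_literature.tsv"))


def load_disease_targets() -> list[TargetRecord]:
    """The 33 curated disease-associated protein targets."""
    return read_target_table(_data_path("disease_targets.tsv"))


def load_reference_drugs() -> pd.DataFrame:
    """Synthetic 200-drug descriptor table standing in for a reference
    approved-drug collection; columns follow DESCRIPTOR_NAMES."""
    df = pd.read_csv(_data_path("reference_drugs_synthetic.tsv"), sep="\t")
    return df[list(DESCRIPTOR_NAMES)]
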