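"""ADME candidate screening.

Two record-level filters select candidate bioactive compounds from a raw
ingredient table: oral bioavailability (OB, a precomputed percentage; the
default cutoff keeps OB >= 30%) and drug-likeness (DL, the Tanimoto
similarity between a compound's property vector and the centroid of a
reference approved-drug collection; default cutoff DL >= 0.18).  Compounds
failing either cutoff can still be retained through an explicit, auditable
rescue list, mirroring literature-justified inclusion of known actives.

A record-level deglycosylation step models intestinal glycosidase
hydrolysis: O-glycosides are cleaved at the anomeric bond and the unique
aglycone products are emitted as ``*_qt`` derivative records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core_model_io import (
    CompoundRecord,
    DescriptorVector,
    ValidationError,
)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "compute_dl",
    "reference_centroid",
    "reference_scale",
    "descriptor_drug_likeness",
    "apply_ob_dl_filter",
    "deglycosylate",
]

ReasonCode = Literal["passed_both", "rescued", "failed_ob", "failed_dl", "failed_both"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and rescue list for the joint OB/DL screen."""

    ob_min: float = 30.0  # percentage, inclusive
    dl_min: float = 0.18  # Tanimoto fraction, inclusive
    rescue_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValidationError(f"ob_min must be >= 0, got {self.ob_min}")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValidationError(f"dl_min must be in [0, 1], got {self.dl_min}")
        object.__setattr__(self, "rescue_ids", frozenset(self.rescue_ids))


@dataclass
class ScreenResult:
    candidates: list[CompoundRecord]
    excluded: list[CompoundRecord]
    reasons: dict[str, ReasonCode]

    @property
    def n_rescued(self) -> int:
        return sum(1 for v in self.reasons.values() if v == "rescued")


def _as_vector(a) -> np.ndarray:
    if isinstance(a, DescriptorVector):
        return a.as_array()
    return np.asarray(a, dtype=float)


def compute_dl(a, b_ref) -> float:
    """Tanimoto similarity F(A, B) = A.B / (|A|^2 + |B|^2 - A.B).

    Symmetric; equals 1 iff the vectors coincide and lies in [0, 1] for
    non-negative inputs.  Accepts DescriptorVector or any 1-d array-like.
    """
    va, vb = _as_vector(a), _as_vector(b_ref)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    dot = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined: both vectors are zero")
    return dot / denom


def reference_centroid(reference_records: Sequence) -> np.ndarray:
    """Component-wise mean of a non-empty list of descriptor vectors."""
    if len(reference_records) == 0:
        raise ValueError("reference set is empty")
    mat = np.vstack([_as_vector(r) for r in reference_records])
    return mat.mean(axis=0)


def reference_scale(reference_records: Sequence) -> np.ndarray:
    """Per-component sample standard deviation of the reference set.

    Zero-variance components get scale 1 so they pass through unscaled.
    """
    mat = np.vstack([_as_vector(r) for r in reference_records])
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.ones(mat.shape[1])
    sd = np.where(sd == 0, 1.0, sd)
    return sd


def descriptor_drug_likeness(
    vec,
    reference_records: Sequence,
    backend: str = "descriptor_zscaled",
) -> float:
    """DL of one compound against a reference collection.

    The default backend divides each descriptor by the reference set's
    per-component standard deviation before the Tanimoto similarity, so
    large-magnitude components (molecular weight, TPSA) do not dominate
    the dot product.  ``backend="descriptor_raw"`` skips the scaling.
    """
    if backend not in ("descriptor_zscaled", "descriptor_raw"):
        raise ValueError(f"unknown DL backend: {backend!r}")
    centroid = reference_centroid(reference_records)
    v = _as_vector(vec)
    if backend == "descriptor_zscaled":
        sd = reference_scale(reference_records)
        v = v / sd
        centroid = centroid / sd
    return compute_dl(v, centroid)


def apply_ob_dl_filter(
    compounds: Iterable[CompoundRecord], cfg: ScreenConfig = ScreenConfig()
) -> ScreenResult:
    """Joint OB/DL screen with explicit rescue.

    A compound is a candidate iff (ob >= ob_min AND dl >= dl_min) or its
    id is in the rescue list; both thresholds are inclusive.  Every input
    record lands in exactly one of candidates/excluded, with a reason code.
    """
    candidates: list[CompoundRecord] = []
    excluded: list[CompoundRecord] = []
    reasons: dict[str, ReasonCode] = {}
    for rec in compounds:
        if rec.ob is None or rec.dl is None:  # defensive; dataclass requires both
            raise ValidationError(f"{rec.compound_id}: missing ob or dl")
        ob_ok = rec.ob >= cfg.ob_min
        dl_ok = rec.dl >= cfg.dl_min
        if ob_ok and dl_ok:
            reasons[rec.compound_id] = "passed_both"
            candidates.append(rec)
        elif rec.compound_id in cfg.rescue_ids:
            reasons[rec.compound_id] = "rescued"
            candidates.append(replace(rec, rescued=True))
        else:
            if not ob_ok and not dl_ok:
                reasons[rec.compound_id] = "failed_both"
            elif not ob_ok:
                reasons[rec.compound_id] = "failed_ob"
            else:
                reasons[rec.compound_id] = "failed_dl"
            excluded.append(rec)
    return ScreenResult(candidates=candidates, excluded=excluded, reasons=reasons)


# ---------------------------------------------------------------------------
# Deglycosylation (record-level, O-glycosides only)
# ---------------------------------------------------------------------------

# Anomeric carbon of a pyranose ring bonded through an exocyclic oxygen to
# any non-hydrogen atom: atom 0 is the aglycone attachment, atom 1 the
# glycosidic oxygen, atom 2 the anomeric carbon.  Two ring hydroxyls are
# required so plain tetrahydropyran ethers do not match.
_GLYCOSIDIC_SMARTS = (
    "[!$([CX4]1[OX2][CX4][CX4][CX4][CX4]1);!#8;!#1]"
    "[OX2][CX4]1[OX2][CX4][CX4]([OX2H,CX4])[CX4]([OX2H])[CX4]1[OX2H]"
)


def _rdkit():
    from rdkit import Chem  # deferred: keeps import cost out of hot paths

    return Chem


def deglycosylate(record: CompoundRecord) -> list[CompoundRecord]:
    """Cleave O-glycosidic sugars and emit aglycone derivative records.

    When a pyranose sugar is attached through an exocyclic glycosidic
    oxygen, every such bond is cleaved (the oxygen stays with the aglycone,
    as in glycosidase hydrolysis), and the unique non-sugar products are
    returned as ``<name>_qt`` records with ``is_aglycone_derivative=True``
    and descriptors cleared for recomputation.  Records without a parsable
    structure or without a sugar are returned unchanged.
    """
    if not record.smiles:
        return [record]
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        warnings.warn(
            f"{record.compound_id}: unparsable SMILES; passed through untouched"
        )
        return [record]
    pattern = Chem.MolFromSmarts(_GLYCOSIDIC_SMARTS)
    matches = mol.GetSubstructMatches(pattern)
    if not matches:
        return [record]
    rw = Chem.RWMol(mol)
    # cleave every glycosidic O - anomeric C bond; O stays on the aglycone
    bonds = set()
    for match in matches:
        o_idx, c_idx = match[1], match[2]
        bonds.add((min(o_idx, c_idx), max(o_idx, c_idx)))
    for a, b in bonds:
        rw.RemoveBond(a, b)
    cleaved = rw.GetMol()
    Chem.SanitizeMol(cleaved)
    sugar_core = Chem.MolFromSmarts("[CX4]1[OX2][CX4][CX4][CX4][CX4]1")
    seen: set[str] = set()
    out: list[CompoundRecord] = []
    for frag in Chem.GetMolFrags(cleaved, asMols=True):
        if frag.HasSubstructMatch(sugar_core):
            continue  # sugar moiety, discarded
        smi = Chem.MolToSmiles(frag)
        if smi in seen:
            continue
        seen.add(smi)
        suffix = "" if len(seen) == 1 else f"_{len(seen)}"
        out.append(
            replace(
                record,
                compound_id=f"{record.compound_id}_qt{suffix}",
                name=f"{record.name}_qt{suffix}",
                smiles=smi,
                descriptors=None,
                is_aglycone_derivative=True,
            )
        )
    return out if out else [record]
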