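"""Physicochemical profiling of compound groups.

Summaries (mean, sample SD) and two-group comparisons over the eight
standard descriptors, with the tiered significance flags used in
property-space comparisons of herbal ingredients against approved drugs
(ns / p<0.05 / p<0.01).  The comparison test is Welch's two-sample t by
default — the groups' variances are visibly unequal — with a permutation
test available both as a config switch and as the validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model_io import DESCRIPTOR_NAMES, DescriptorVector

__all__ = [
    "DescriptorSummary",
    "summarize_group",
    "compare_groups",
    "permutation_pvalue",
    "histogram_counts",
    "summary_frame",
]

Flag = Literal["ns", "p<0.05", "p<0.01"]


@dataclass
class DescriptorSummary:
    """Per-descriptor means/SDs for one or two groups, plus comparison."""

    n_a: int
    mean_a: dict[str, float]
    sd_a: dict[str, float]
    n_b: Optional[int] = None
    mean_b: Optional[dict[str, float]] = None
    sd_b: Optional[dict[str, float]] = None
    p_value: Optional[dict[str, float]] = None
    flag: Optional[dict[str, Flag]] = None


def _matrix(vectors: Sequence) -> np.ndarray:
    if len(vectors) == 0:
        raise ValueError("empty descriptor group")
    rows = []
    for v in vectors:
        rows.append(v.as_array() if isinstance(v, DescriptorVector) else
                    np.asarray(v, dtype=float))
    return np.vstack(rows)


def _flag(p: float) -> Flag:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def summarize_group(vectors: Sequence) -> DescriptorSummary:
    """Arithmetic mean and sample SD (n-1 denominator) per descriptor."""
    mat = _matrix(vectors)
    sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    return DescriptorSummary(
        n_a=mat.shape[0],
        mean_a=dict(zip(DESCRIPTOR_NAMES, mat.mean(axis=0))),
        sd_a=dict(zip(DESCRIPTOR_NAMES, sd)),
    )


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0  # identical samples: no evidence of difference
    res = stats.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant; compare the constants
        return 1.0 if x[0] == y[0] else 0.0
    return p


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for a difference in group means."""
    res = stats.permutation_test(
        (np.asarray(x, float), np.asarray(y, float)),
        lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=n_resamples,
        vectorized=True,
        rng=seed,
    )
    return float(res.pvalue)


def compare_groups(
    a: Sequence,
    b: Sequence,
    test: str = "welch",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> DescriptorSummary:
    """Per-descriptor two-sample comparison with tiered significance flags.

    ``test`` is ``"welch"`` (default) or ``"permutation"``.  Flags are
    mutually exclusive tiers: a descriptor at p<0.01 is flagged p<0.01
    only.  Both groups must have at least two members.
    """
    mat_a, mat_b = _matrix(a), _matrix(b)
    if mat_a.shape[0] < 2 or mat_b.shape[0] < 2:
        raise ValueError("both groups must have size >= 2")
    if test not in ("welch", "permutation"):
        raise ValueError(f"unknown test: {test!r}")
    pvals: dict[str, float] = {}
    for j, name in enumerate(DESCRIPTOR_NAMES):
        x, y = mat_a[:, j], mat_b[:, j]
        if test == "welch":
            pvals[name] = _welch_p(x, y)
        else:
            pvals[name] = permutation_pvalue(x, y, n_resamples, seed)
    sd_a = mat_a.std(axis=0, ddof=1)
    sd_b = mat_b.std(axis=0, ddof=1)
    return DescriptorSummary(
        n_a=mat_a.shape[0],
        mean_a=dict(zip(DESCRIPTOR_NAMES, mat_a.mean(axis=0))),
        sd_a=dict(zip(DESCRIPTOR_NAMES, sd_a)),
        n_b=mat_b.shape[0],
        mean_b=dict(zip(DESCRIPTOR_NAMES, mat_b.mean(axis=0))),
        sd_b=dict(zip(DESCRIPTOR_NAMES, sd_b)),
        p_value=pvals,
        flag={k: _flag(p) for k, p in pvals.items()},
    )


def histogram_counts(
    vectors: Sequence, descriptor: str, bins: int = 20
) -> pd.DataFrame:
    """Histogram table (bin_left, bin_right, count) for one descriptor.

    Bin counts always sum to the group size.
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise ValueError(f"unknown descriptor: {descriptor!r}")
    j = DESCRIPTOR_NAMES.index(descriptor)
    x = _matrix(vectors)[:, j]
    counts, edges = np.histogram(x, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def summary_frame(summary: DescriptorSummary,
                  group_a: str = "a", group_b: str = "b") -> pd.DataFrame:
    """Flatten a two-group DescriptorSummary into a tidy table."""
    rows = []
    for name in DESCRIPTOR_NAMES:
        rows.append({
            "descriptor": name, "group": group_a,
            "mean": summary.mean_a[name], "sd": summary.sd_a[name],
            "p": summary.p_value[name] if summary.p_value else None,
            "flag": summary.flag[name] if summary.flag else None,
        })
        if summary.mean_b is not None:
            rows.append({
                "descriptor": name, "group": group_b,
                "mean": summary.mean_b[name], "sd": summary.sd_b[name],
                "p": summary.p_value[name] if summary.p_value else None,
                "flag": summary.flag[name] if summary.flag else None,
            })
    return pd.DataFrame(rows)


def descriptors_from_smiles(smiles: str) -> DescriptorVector:
    """Approximate descriptor vector from structure (Ertl TPSA;
    Wildman-Crippen logP standing in for the Moriguchi estimate).  An
    approximation of commercial descriptor software, offered for records
    lacking precomputed values."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    nhdon = Lipinski.NumHDonors(mol)
    nhacc = Lipinski.NumHAcceptors(mol)
    # hydrophilic factor from hydrophilic-group and heavy-atom counts
    n_heavy = mol.GetNumHeavyAtoms()
    n_hy = sum(
        1 for atom in mol.GetAtoms()
        if atom.GetSymbol() in ("O", "N") and atom.GetTotalNumHs() > 0
    )
    nsk = max(n_heavy, 1)
    hy = (
        (1 + n_hy) * np.log2(1 + n_hy)
        + nsk * (1 / nsk * np.log2(1 / nsk))
        + np.sqrt(n_hy / nsk**2)
    ) / np.log2(1 + nsk)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        ncic=rdMolDescriptors.CalcNumRings(mol),
        nhdon=nhdon,
        nhacc=nhacc,
        rbn=Lipinski.NumRotatableBonds(mol),
        hy=float(hy),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        mlogp=float(Crippen.MolLogP(mol)),
    )
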