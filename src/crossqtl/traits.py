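"""Trait-matrix processing: normalisation, replicate handling and
residual-layer derivation.

All molecular trait matrices are samples-or-strains x traits on log2
scale.  Residual layers remove the part of a child trait explained by its
parent trait: ``pt`` (post-transcriptional; protein regressed on its
transcript) and ``phRes`` (phospho-residual; phosphopeptide regressed on
the protein of origin).  Regression runs at sample level with a robust MM
estimate; residuals are then averaged per strain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .robust import PairSkipped, center_scale_shared, mm_regress

__all__ = [
    "LAYERS",
    "length_normalize",
    "batch_center",
    "average_replicates",
    "residual_traits",
    "phosphosite_composition",
]

#: recognised layer tags
LAYERS = ("transcript", "protein", "phospho", "pt", "phRes")


def length_normalize(counts_log2: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Correct log2 expression for coding-region length.

    c' = log2(2^c * 1000 / l) = c + log2(1000 / l), i.e. expression per
    kilobase of coding sequence.  Genes without a length are dropped with
    a warning.
    """
    lengths = lengths.dropna()
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    missing = [g for g in counts_log2.columns if g not in lengths.index]
    if missing:
        warnings.warn(f"dropping {len(missing)} traits without a gene length")
    kept = [g for g in counts_log2.columns if g in lengths.index]
    out = counts_log2[kept].copy()
    offset = np.log2(1000.0 / lengths.loc[kept].to_numpy(dtype=float))
    return out + offset


def batch_center(samples: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Remove additive batch effects by per-batch mean centring.

    Per trait, each batch's mean is subtracted and the grand mean added
    back, so per-batch trait means are equal afterwards.  Missing values
    are ignored in the means.
    """
    batches = design.set_index("sample")["batch"]
    if not set(samples.index).issubset(batches.index):
        raise ValueError("every sample needs a batch label")
    b = batches.loc[samples.index]
    sizes = b.value_counts()
    if (sizes == 1).any():
        warnings.warn("batches of size 1 are centred onto the grand mean")
    grand = samples.mean(axis=0, skipna=True)
    out = samples.copy()
    for batch, idx in samples.groupby(b.to_numpy()).groups.items():
        out.loc[idx] = samples.loc[idx] - samples.loc[idx].mean(axis=0, skipna=True) + grand
    return out


def average_replicates(samples: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over each strain's samples, ignoring missing values.

    Strains are returned in lexicographic order.  A strain whose samples
    are all missing for a trait propagates NaN.
    """
    strain = design.set_index("sample")["strain"]
    if not set(samples.index).issubset(strain.index):
        raise ValueError("design does not cover all samples")
    grouped = samples.groupby(strain.loc[samples.index].to_numpy()).mean()
    return grouped.sort_index()


def residual_traits(
    child: pd.DataFrame,
    parent: pd.DataFrame,
    mapping: pd.Series,
    design: pd.DataFrame,
    layer: str | None = None,
    min_shared: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive residual traits of a child layer given its parent layer.

    For each child trait with a mapped, measured parent trait:
    standardise both sample-level vectors on their shared samples, fit a
    robust MM regression of child on parent, take the residuals and
    average them per strain.  Returns ``(residual_matrix, skip_log)``;
    the skip log lists pairs dropped for too few shared samples or
    degenerate spread.

    ``mapping`` maps child trait id -> parent trait id (e.g. peptide to
    protein of origin, or protein to transcript).
    """
    if not set(child.index).issubset(set(parent.index)):
        raise ValueError("child and parent must share the sample axis")
    parent = parent.loc[child.index]
    out: dict[str, np.ndarray] = {}
    skipped = []
    strain = design.set_index("sample")["strain"].loc[child.index]
    for trait in child.columns:
        pid = mapping.get(trait)
        if pid is None or pid not in parent.columns:
            skipped.append((trait, "no_parent"))
            continue
        try:
            x_std, y_std, shared = center_scale_shared(
                parent[pid].to_numpy(), child[trait].to_numpy(), min_shared)
            fit = mm_regress(y_std[shared], x_std[shared])
        except PairSkipped as exc:
            skipped.append((trait, exc.reason))
            continue
        resid = np.full(len(child), np.nan)
        resid[shared] = fit.residuals
        out[trait] = resid
    resid_samples = pd.DataFrame(out, index=child.index)
    resid_strain = resid_samples.groupby(strain.to_numpy()).mean().sort_index()
    resid_strain.attrs["layer"] = layer or "residual"
    skip_log = pd.DataFrame(skipped, columns=["trait", "reason"])
    return resid_strain, skip_log


def phosphosite_composition(residues: pd.Series | list[str]) -> pd.DataFrame:
    """Counts and percentages of phosphosite residue types (S, T, Y).

    Percentages are rounded to one decimal.  Unknown residue labels are
    rejected.
    """
    s = pd.Series(list(residues), dtype=str)
    unknown = sorted(set(s) - {"S", "T", "Y"})
    if unknown:
        raise ValueError(f"unknown residue labels: {unknown}")
    counts = s.value_counts().reindex(["S", "T", "Y"], fill_value=0)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no sites given")
    pct = (counts / total * 100.0).round(1)
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})
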