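"""Linking molecular layers to physiological traits.

Three tools: top-correlator extraction (which molecular layer best
predicts a physiological trait), linear-model mediation with a
nonparametric bootstrap (does a molecular trait transmit a locus effect
to a physiological outcome), and one-sided Fisher enrichment machinery
used for set-overlap questions throughout.

The mediation estimator is the product-of-coefficients method: with a
binary genotype x, mediator m and outcome y, fit m ~ x (coefficient a)
and y ~ x + m (coefficients c' and b); the average causal mediation
effect is ACME = a*b, the direct effect ADE = c', and total = a*b + c'.
Under linear models without exposure-mediator interaction this coincides
with the counterfactual ACME.  P-values come from a percentile bootstrap
over strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import ZeroVarianceError, marker_relationship

__all__ = [
    "MediationResult",
    "aggregate_phospho_by_protein",
    "top_correlators",
    "mediate_acme",
    "fisher_enrichment",
    "shared_qtl_site_pairs",
    "classify_functional_peptides",
]


def aggregate_phospho_by_protein(
    peptides: pd.DataFrame,
    mapping: pd.Series,
) -> pd.DataFrame:
    """Protein-level phospho traits: mean of z-scored peptides.

    Each peptide column is standardised across strains and peptides of
    the same protein (per ``mapping``: peptide -> protein) averaged.
    Zero-variance peptides are dropped with a warning.
    """
    cols = {}
    dropped = []
    for pep in peptides.columns:
        v = peptides[pep].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            dropped.append(pep)
            continue
        cols[pep] = (v - np.nanmean(v)) / sd
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance peptides")
    z = pd.DataFrame(cols, index=peptides.index)
    prot = mapping.loc[[p for p in z.columns]]
    return z.T.groupby(prot.to_numpy()).mean().T


def _pairwise_pearson(a: np.ndarray, B: np.ndarray, min_shared: int) -> np.ndarray:
    """Pearson r of vector a against each column of B, pairwise-complete."""
    out = np.full(B.shape[1], np.nan)
    for j in range(B.shape[1]):
        b = B[:, j]
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < min_shared:
            continue
        x, y = a[ok], b[ok]
        if x.std() == 0 or y.std() == 0:
            continue
        out[j] = np.corrcoef(x, y)[0, 1]
    return out


def top_correlators(
    layers: dict[str, pd.DataFrame],
    physio: pd.DataFrame,
    gene_maps: dict[str, pd.Series] | None = None,
    min_shared: int = 10,
    use_abs: bool = True,
    low_r_flag: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Best-correlated molecular feature per layer for each physiological
    trait, and per-layer win counts.

    When ``gene_maps`` (layer -> Series mapping trait id to gene) is
    given, each layer is restricted to genes measured on every layer so
    the comparison is fair.  Ranking uses |r| by default (set ``use_abs``
    False for signed r).  Rows with best |r| below ``low_r_flag`` are
    flagged as weak.
    """
    layers = dict(layers)
    if gene_maps is not None:
        common = None
        for layer, gm in gene_maps.items():
            genes = set(gm.loc[[t for t in layers[layer].columns if t in gm.index]])
            common = genes if common is None else (common & genes)
        for layer, gm in gene_maps.items():
            keep = [t for t in layers[layer].columns
                    if t in gm.index and gm[t] in common]
            layers[layer] = layers[layer][keep]
    rows = []
    for ptrait in physio.columns:
        best_layer, best_feature, best_r = None, None, np.nan
        per_layer = {}
        for layer, df in layers.items():
            shared = df.index.intersection(physio.index)
            if len(shared) < min_shared:
                continue
            r = _pairwise_pearson(physio.loc[shared, ptrait].to_numpy(),
                                  df.loc[shared].to_numpy(), min_shared)
            if np.all(np.isnan(r)):
                continue
            score = np.abs(r) if use_abs else r
            j = int(np.nanargmax(score))
            per_layer[layer] = (df.columns[j], float(r[j]))
            if best_r is np.nan or np.isnan(best_r) or score[j] > (abs(best_r) if use_abs else best_r):
                best_layer, best_feature, best_r = layer, df.columns[j], float(r[j])
        if best_layer is None:
            continue
        row = {"physio_trait": ptrait, "winner_layer": best_layer,
               "winner_feature": best_feature, "winner_r": best_r,
               "weak": abs(best_r) < low_r_flag}
        for layer, (feat, r) in per_layer.items():
            row[f"best_{layer}"] = feat
            row[f"r_{layer}"] = r
        rows.append(row)
    report = pd.DataFrame(rows)
    wins = (report["winner_layer"].value_counts()
            if len(report) else pd.Series(dtype=int))
    return report, wins


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    proportion_mediated: float
    p_acme: float
    p_ade: float
    p_total: float
    n_boot: int


def _product_method(x, m, y):
    a = np.polyfit(x, m, 1)[0]
    resid_m = m - np.polyval(np.polyfit(x, m, 1), x)
    if np.var(resid_m) <= 1e-24 * max(np.var(m), 1.0):
        # mediator fully determined by the genotype: y ~ x + m is rank
        # deficient and the decomposition unidentified; attribute the
        # effect to the mediated path (b from y ~ m, no direct term)
        b = np.polyfit(m, y, 1)[0] if np.var(m) > 0 else 0.0
        return a * b, 0.0
    X = np.column_stack([np.ones_like(x), x, m])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c_prime, b = coef[1], coef[2]
    return a * b, c_prime


def _percentile_p(boot: np.ndarray) -> float:
    n = len(boot)
    lo = (1 + (boot <= 0).sum()) / (1 + n)
    hi = (1 + (boot >= 0).sum()) / (1 + n)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mediate_acme(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 999,
    seed: int = 0,
) -> MediationResult:
    """Average causal mediation effect of binary genotype x on outcome y
    through mediator m, with percentile-bootstrap two-sided p-values.

    Complete cases only; x must take both values.  Deterministic for a
    fixed seed.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(m) & ~np.isnan(y)
    x, m, y = x[ok], m[ok], y[ok]
    if len(np.unique(x)) < 2:
        raise ValueError("genotype must take both alleles")
    acme, ade = _product_method(x, m, y)
    total = acme + ade
    prop = acme / total if total != 0 else np.nan
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty((n_boot, 3))
    b = 0
    attempts = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        attempts += 1
        if attempts > 10 * n_boot:
            raise RuntimeError("bootstrap failed to find non-degenerate resamples")
        if len(np.unique(x[idx])) < 2:
            continue
        a_b, d_b = _product_method(x[idx], m[idx], y[idx])
        boots[b] = (a_b, d_b, a_b + d_b)
        b += 1
    return MediationResult(
        acme=float(acme), ade=float(ade), total=float(total),
        proportion_mediated=float(prop),
        p_acme=_percentile_p(boots[:, 0]),
        p_ade=_percentile_p(boots[:, 1]),
        p_total=_percentile_p(boots[:, 2]),
        n_boot=n_boot,
    )


def fisher_enrichment(hits: set, annotated: set, universe: set) -> tuple[float, float]:
    """One-sided (greater) Fisher's exact test for overlap of two sets.

    Returns the sample odds ratio (inf when the off-diagonal is empty)
    and the hypergeometric tail p-value.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (hits <= universe and annotated <= universe):
        raise ValueError("hits and annotated must be subsets of the universe")
    a = len(hits & annotated)
    b = len(hits - annotated)
    c = len(annotated - hits)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    odds = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else a * d / (b * c))
    return float(odds), float(p)


def shared_qtl_site_pairs(
    phres_qtls: pd.DataFrame,
    site_protein: pd.Series,
    calls: pd.DataFrame,
    r_threshold: float = 0.8,
) -> tuple[float, float, float]:
    """Do phosphosites on the same protein share QTLs more than random
    pairs of sites?

    A pair of sites "shares" when their QTL member-marker sets overlap or
    contain a cross pair with genotype correlation r > ``r_threshold``.
    Returns (proportion same-protein pairs sharing, proportion
    different-protein pairs sharing, one-sided Fisher p).
    """
    traits = sorted(set(phres_qtls["trait"]) | set(site_protein.index))
    members: dict[str, list[str]] = {t: [] for t in traits}
    for _, row in phres_qtls.iterrows():
        members[row["trait"]].extend(row["members"].split(","))
    same = {"share": 0, "total": 0}
    diff = {"share": 0, "total": 0}
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            bucket = same if site_protein.get(t1) == site_protein.get(t2) else diff
            bucket["total"] += 1
            if members[t1] and members[t2] and _sets_linked(
                    members[t1], members[t2], calls, r_threshold):
                bucket["share"] += 1
    p_same = same["share"] / same["total"] if same["total"] else 0.0
    p_diff = diff["share"] / diff["total"] if diff["total"] else 0.0
    table = [[same["share"], same["total"] - same["share"]],
             [diff["share"], diff["total"] - diff["share"]]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return p_same, p_diff, float(p)


def _sets_linked(a: list[str], b: list[str], calls: pd.DataFrame,
                 r_threshold: float) -> bool:
    if set(a) & set(b):
        return True
    for ma in a:
        va = calls[ma].to_numpy()
        for mb in b:
            try:
                r, _ = marker_relationship(va, calls[mb].to_numpy())
            except ZeroVarianceError:
                continue
            if r > r_threshold:
                return True
    return False


def classify_functional_peptides(
    peptide_sites: dict[str, list[tuple[str, int]]],
    significant_sites: set[tuple[str, int]],
    tested_sites: set[tuple[str, int]],
) -> pd.Series:
    """Label peptides by overlap with fitness-assayed phosphosites.

    functional — carries at least one site with a significant fitness
    effect; non_functional — all sites were assayed and none significant;
    untested — otherwise.  Sites are (protein, residue position) keys.
    """
    labels = {}
    for pep, sites in peptide_sites.items():
        if any(s in significant_sites for s in sites):
            labels[pep] = "functional"
        elif sites and all(s in tested_sites for s in sites):
            labels[pep] = "non_functional"
        else:
            labels[pep] = "untested"
    return pd.Series(labels, name="functional_class")
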