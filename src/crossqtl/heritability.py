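"""Broad-sense heritability from replicated strains.

H2 = sigma_G^2 / (sigma_G^2 + sigma_E^2), where sigma_G^2 is the variance
between strains (all strain-level differences, genetic in a panel of
genetically distinct clonal strains) and sigma_E^2 the residual variance
among replicate cultures of the same strain.  Estimation uses the one-way
random-effects method of moments restricted to strains with at least two
replicates:

    sigma_E^2 = pooled within-strain variance (the within mean square)
    sigma_G^2 = max(0, (MS_between - MS_within) / n0)

with the unbalanced-design effective replicate number
n0 = (N - sum n_i^2 / N) / (k - 1).  On balanced designs this is exactly
the classical ANOVA estimator; a full mixed-model fit is equivalent in
expectation for this one-way layout.  Standard errors come from a
delete-one-strain jackknife, and significance from permuting strain
labels among the replicated samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "H2Result",
    "variance_components",
    "broad_sense_h2",
    "jackknife_se",
    "h2_permutation_null",
    "h2_table",
]


@dataclass
class H2Result:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se: float | None = None
    p_value: float | None = None
    defined: bool = True


def _replicated(values: np.ndarray, labels: np.ndarray):
    """Group samples of strains with >= 2 non-missing replicates."""
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    groups = {}
    for v, lab in zip(values, labels):
        groups.setdefault(lab, []).append(v)
    groups = {k: np.asarray(v) for k, v in groups.items() if len(v) >= 2}
    return groups


def variance_components(values, strain_labels) -> tuple[float, float]:
    """(sigma_G^2, sigma_E^2) by one-way random-effects method of moments.

    Only strains with at least two replicates enter; at least two such
    strains are required.  Negative genetic-variance estimates are
    truncated at zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(strain_labels)
    groups = _replicated(values, labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 strains with >= 2 replicates")
    ns = np.array([len(v) for v in groups.values()], dtype=float)
    means = np.array([v.mean() for v in groups.values()])
    N = ns.sum()
    grand = sum(v.sum() for v in groups.values()) / N
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ms_within = ss_within / (N - k)
    ms_between = float((ns * (means - grand) ** 2).sum() / (k - 1))
    n0 = (N - (ns ** 2).sum() / N) / (k - 1)
    sigma_g2 = max(0.0, (ms_between - ms_within) / n0)
    return float(sigma_g2), float(ms_within)


def broad_sense_h2(values, strain_labels) -> H2Result:
    """H2 = sigma_G^2 / (sigma_G^2 + sigma_E^2), clipped to [0, 1]."""
    sg2, se2 = variance_components(values, strain_labels)
    total = sg2 + se2
    if total == 0.0:
        return H2Result(sg2, se2, np.nan, defined=False)
    return H2Result(sg2, se2, float(np.clip(sg2 / total, 0.0, 1.0)))


def jackknife_se(values, strain_labels) -> float:
    """Delete-one-strain jackknife standard error of H2.

    Each replicated strain is removed in turn (with all its samples) and
    H2 recomputed; deletions that leave the estimator undefined are
    skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(strain_labels)
    reps = list(_replicated(values, labels))
    if len(reps) < 3:
        raise ValueError("jackknife needs >= 3 replicated strains")
    estimates = []
    for strain in reps:
        keep = labels != strain
        try:
            res = broad_sense_h2(values[keep], labels[keep])
        except ValueError:
            import warnings
            warnings.warn(f"leave-one-out failed for strain {strain!r}; skipped")
            continue
        if res.defined:
            estimates.append(res.h2)
    est = np.asarray(estimates)
    kk = len(est)
    if kk < 2:
        raise ValueError("too few valid leave-one-out estimates")
    return float(np.sqrt((kk - 1) / kk * ((est - est.mean()) ** 2).sum()))


def h2_permutation_null(values, strain_labels, n_perm: int = 99,
                        seed: int = 0) -> tuple[np.ndarray, float]:
    """Permute strain labels among samples; one-sided p for the observed H2.

    p = (1 + #{null >= observed}) / (1 + n_perm), always in (0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(strain_labels)
    observed = broad_sense_h2(values, labels).h2
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = broad_sense_h2(values, rng.permutation(labels)).h2
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    return null, p


def h2_table(samples: pd.DataFrame, design: pd.DataFrame,
             n_perm: int = 0, seed: int = 0) -> pd.DataFrame:
    """Heritability of every trait column of a sample-level matrix.

    ``design`` maps sample -> strain.  Jackknife SEs are always computed;
    permutation p-values only when ``n_perm`` > 0.
    """
    strain = design.set_index("sample")["strain"].loc[samples.index].to_numpy()
    rows = []
    for trait in samples.columns:
        v = samples[trait].to_numpy(dtype=float)
        res = broad_sense_h2(v, strain)
        try:
            se = jackknife_se(v, strain)
        except ValueError:
            se = np.nan
        p = np.nan
        if n_perm > 0:
            _, p = h2_permutation_null(v, strain, n_perm, seed)
        rows.append((trait, res.sigma_g2, res.sigma_e2, res.h2, se, p))
    return pd.DataFrame(
        rows, columns=["trait", "sigma_g2", "sigma_e2", "h2", "se", "p_value"])
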