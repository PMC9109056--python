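"""Random-Forest QTL mapping with permutation-based empirical FDR.

Each strain-level trait is modelled by a regression forest on all
collapsed markers plus population-structure covariates.  Two variable
importance measures are combined per predictor i:

* RSS_i — mean over trees of the total decrease in node sum of squared
  residuals contributed by splits on predictor i;
* PI_i — mean over trees of the increase in out-of-bag squared error
  after permuting predictor i within the tree's out-of-bag samples (the
  reduction in predictive accuracy relative to the intact predictor; the
  raw-difference form is used rather than a ratio to the base error,
  which would blow up whenever a strong covariate drives the base error
  towards zero);

and the score is their positive-part product

    S_i = max(0, RSS_i) * max(0, PI_i).

Significance comes from an empirical null: the trait vector is permuted
across strains (genotypes and covariates stay attached to each other,
because the covariates are functions of the genotype matrix), the forest
rerun, and the scores recorded.  For a threshold s the estimated FDR is
the mean number of null scores >= s per permutation divided by the number
of observed scores >= s; a marker's q-value is the minimum estimated FDR
over all thresholds below its own score, which makes q monotone
non-increasing in S.  Covariate importances are computed but never
reported as QTLs.

Significant markers are merged into linkages: markers that are adjacent
on the unique-marker map, or in high LD (Pearson r > 0.8), and linked to
the same trait count as a single QTL whose peak is the member with
maximal S (ties broken towards the smaller genomic coordinate).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from sklearn.tree import DecisionTreeRegressor

from .genotype import UniqueMarkerSet

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "VIMScores",
    "combined_score",
    "forest_importances",
    "permutation_null",
    "estimate_fdr",
    "pooled_linkage_fdr",
    "linkage_count_curve",
    "call_qtls",
    "map_traits",
]


@dataclass
class ForestConfig:
    """Forest and permutation-test settings.

    ``max_features_frac`` is the fraction of predictors considered per
    split (default one third, the usual regression-forest rule);
    ``n_permutations`` controls the empirical null (>= 20 required).
    """

    n_trees: int = 500
    max_features_frac: float = 1.0 / 3.0
    min_samples_leaf: int = 5
    n_permutations: int = 200
    fdr_threshold: float = 0.10
    ld_r: float = 0.8
    seed: int = 0
    #: estimate the FDR pooled across traits and counted at the linkage
    #: level (merged significant-marker groups) rather than per trait at
    #: marker level; see pooled_linkage_fdr
    pooled: bool = True

    def __post_init__(self):
        if self.n_permutations < 20:
            raise ValueError("need at least 20 permutations")
        if not 0 < self.max_features_frac <= 1:
            raise ValueError("max_features_frac must be in (0, 1]")


@dataclass
class VIMScores:
    """Per-predictor importances of one forest."""

    rss: np.ndarray
    pi: np.ndarray
    s: np.ndarray
    constant_trait: bool = False


def combined_score(rss: np.ndarray | float, pi: np.ndarray | float):
    """S = max(0, RSS) * max(0, PI)."""
    return np.maximum(0.0, rss) * np.maximum(0.0, pi)


def _as_float32(X: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(X, dtype=np.float32)


def forest_importances(
    y: np.ndarray,
    X: np.ndarray,
    config: ForestConfig,
    seed: int | np.random.Generator = 0,
) -> VIMScores:
    """Grow a regression forest and return RSS, PI and combined scores.

    ``X`` holds all predictors (markers first, then any covariates) and
    must be NA-free; strains with a missing trait value are expected to be
    dropped by the caller.  A constant trait yields all-zero scores with
    ``constant_trait`` set.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y must be NA-free (drop missing strains first)")
    X32 = _as_float32(X)
    if np.isnan(X32).any():
        raise ValueError("predictors must be NA-free")
    n, p = X32.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if y.std() == 0.0:
        return VIMScores(np.zeros(p), np.zeros(p), np.zeros(p), True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_features = max(1, int(config.max_features_frac * p))

    rss_sum = np.zeros(p)
    pi_sum = np.zeros(p)
    n_pi_trees = 0
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        rss_sum, pi_sum, n_pi_trees = _grow(
            y, X32, config, rng, max_features, rss_sum, pi_sum)
    rss = rss_sum / config.n_trees
    pi = pi_sum / max(n_pi_trees, 1)
    return VIMScores(rss, pi, combined_score(rss, pi))


def _grow(y, X32, config, rng, max_features, rss_sum, pi_sum):
    n = len(y)
    n_pi_trees = 0
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X32[idx], y[idx], check_input=False)
        t = tree.tree_
        left, right, feat = t.children_left, t.children_right, t.feature
        internal = left != -1
        if internal.any():
            w = t.weighted_n_node_samples
            imp = t.impurity
            dec = (w * imp)[internal] - (w * imp)[left[internal]] - (w * imp)[right[internal]]
            np.add.at(rss_sum, feat[internal], dec)

        # out-of-bag permutation importance
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        m = int(oob.sum())
        if m < 2 or not internal.any():
            continue
        X_oob = X32[oob]
        y_oob = y[oob]
        base_err = float(np.mean((y_oob - tree.predict(X_oob, check_input=False)) ** 2))
        used = np.unique(feat[internal])
        Xbig = np.tile(X_oob, (len(used), 1))
        for k, f in enumerate(used):
            Xbig[k * m:(k + 1) * m, f] = rng.permutation(X_oob[:, f])
        preds = tree.predict(_as_float32(Xbig), check_input=False)
        errs = ((preds.reshape(len(used), m) - y_oob[None, :]) ** 2).mean(axis=1)
        pi_sum[used] += errs - base_err
        n_pi_trees += 1
    return rss_sum, pi_sum, n_pi_trees


def permutation_null(
    y: np.ndarray,
    X: np.ndarray,
    config: ForestConfig,
    seed: int = 0,
) -> np.ndarray:
    """Null combined-score matrix (n_permutations x predictors).

    Permutation b permutes the trait across strains with a generator
    seeded deterministically from (seed, b) and reruns the forest, so the
    matrix is reproducible bitwise for a given seed.
    """
    y = np.asarray(y, dtype=float)
    null = np.empty((config.n_permutations, X.shape[1]))
    for b in range(config.n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        y_perm = rng.permutation(y)
        null[b] = forest_importances(y_perm, X, config, rng).s
    return null


def estimate_fdr(s_obs: np.ndarray, s_null: np.ndarray) -> np.ndarray:
    """Per-marker empirical q-values from observed and null scores.

    FDR(s) = mean over permutations of #{null S >= s} / #{observed S >= s};
    q_i = min over thresholds s <= S_i of FDR(s), clipped to [0, 1].
    Markers with S <= 0 get q = 1.
    """
    s_obs = np.asarray(s_obs, dtype=float)
    if s_null.ndim != 2:
        raise ValueError("null must be a permutations x predictors matrix")
    n_perm = s_null.shape[0]
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    q = np.ones(len(s_obs))
    pos = s_obs > 0
    if not pos.any():
        return q
    thresholds = np.unique(s_obs[pos])  # ascending
    obs_sorted = np.sort(s_obs)
    null_sorted = np.sort(s_null.ravel())
    n_obs_ge = len(s_obs) - np.searchsorted(obs_sorted, thresholds, side="left")
    mean_null_ge = (len(null_sorted)
                    - np.searchsorted(null_sorted, thresholds, side="left")) / n_perm
    fdr = np.clip(mean_null_ge / n_obs_ge, 0.0, 1.0)
    q_at = np.minimum.accumulate(fdr)  # running min from smallest threshold up
    idx = np.searchsorted(thresholds, s_obs[pos])
    q[pos] = q_at[idx]
    return q


def _ld_partner_lists(calls: pd.DataFrame, ld_r: float) -> list[np.ndarray]:
    """Per marker, the indices of other markers with Pearson r > ld_r."""
    G = calls.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(G, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    return [np.flatnonzero(corr[i] > ld_r) for i in range(G.shape[1])]


def linkage_count_curve(
    scores: np.ndarray,
    chrom_codes: np.ndarray,
    partners: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Number of merged linkages as a function of the score threshold.

    Markers are activated in descending score order; a linkage is a
    connected component of active markers under map adjacency (same
    chromosome) and LD partnership.  Returns ``(act_scores, counts)``
    where ``counts[k]`` is the component count once all markers with
    score >= ``act_scores[k]`` (descending, positive only) are active.
    """
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    order = order[s[order] > 0]
    p = len(s)
    parent = np.arange(p)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    active = np.zeros(p, dtype=bool)
    count = 0
    counts = np.empty(len(order), dtype=np.int64)
    for k, i in enumerate(order):
        active[i] = True
        count += 1
        neigh = []
        if i > 0 and chrom_codes[i - 1] == chrom_codes[i]:
            neigh.append(i - 1)
        if i + 1 < p and chrom_codes[i + 1] == chrom_codes[i]:
            neigh.append(i + 1)
        for j in list(partners[i]) + neigh:
            if active[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
                    count -= 1
        counts[k] = count
    return s[order], counts


def _counts_at(act_scores: np.ndarray, counts: np.ndarray,
               thresholds: np.ndarray) -> np.ndarray:
    """Evaluate a linkage-count step function at given thresholds."""
    # number of activations with score >= t
    j = np.searchsorted(-act_scores, -thresholds, side="right")
    out = np.zeros(len(thresholds), dtype=float)
    nz = j > 0
    out[nz] = counts[j[nz] - 1]
    return out


def pooled_linkage_fdr(
    obs_scores: list[np.ndarray],
    null_scores: list[np.ndarray],
    calls: pd.DataFrame,
    marker_chroms: np.ndarray,
    ld_r: float = 0.8,
) -> list[np.ndarray]:
    """Linkage-level empirical FDR pooled across traits.

    For a score threshold s, the observed linkage count R(s) sums the
    merged significant-marker groups over all traits, and the null count
    V(s) averages the same quantity over the permutation forests of every
    trait.  FDR(s) = V(s)/R(s); a marker's q-value is the minimum FDR
    over thresholds below its own score.  Pooling makes the estimator's
    resolution scale with the number of traits, and counting linkages
    rather than markers matches the unit in which QTLs are reported, so
    the nominal threshold controls the false-discovery proportion of the
    reported calls.  Returns per-trait marker q-value vectors.
    """
    codes = pd.factorize(marker_chroms)[0]
    partners = _ld_partner_lists(calls, ld_r)
    grid = np.unique(np.concatenate([s[s > 0] for s in obs_scores] or [np.array([])]))
    if len(grid) == 0:
        return [np.ones_like(s) for s in obs_scores]
    R = np.zeros(len(grid))
    V = np.zeros(len(grid))
    for s in obs_scores:
        R += _counts_at(*linkage_count_curve(s, codes, partners), grid)
    for null in null_scores:
        B = null.shape[0]
        for b in range(B):
            V += _counts_at(*linkage_count_curve(null[b], codes, partners), grid) / B
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(R > 0, V / R, 1.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    q_at = np.minimum.accumulate(fdr)  # grid ascending: running min upward
    out = []
    for s in obs_scores:
        q = np.ones(len(s))
        pos = s > 0
        q[pos] = q_at[np.searchsorted(grid, s[pos])]
        out.append(q)
    return out


QTL_COLUMNS = ["trait", "layer", "chrom", "start_bp", "end_bp", "peak_marker",
               "peak_pos_bp", "peak_s", "q_value", "effect", "n_markers", "members"]


def call_qtls(
    trait: str,
    layer: str,
    q_values: np.ndarray,
    s_obs: np.ndarray,
    unique_markers: UniqueMarkerSet,
    fdr_threshold: float = 0.10,
    ld_r: float = 0.8,
    trait_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Merge significant markers into QTL linkages for one trait.

    Markers with q <= threshold are grouped by the transitive closure of
    (i) adjacency on the unique-marker map and (ii) pairwise Pearson
    r > ``ld_r`` (the LD rule may join markers on different chromosomes).
    When ``trait_values`` (strain-indexed) is given, the allele effect at
    the peak marker (mean BY minus mean RM, log2 scale) is attached.
    """
    markers = unique_markers.markers
    tab = unique_markers.table.set_index("unique_marker")
    sig = np.flatnonzero(np.asarray(q_values) <= fdr_threshold)
    if len(sig) == 0:
        return pd.DataFrame(columns=QTL_COLUMNS)
    calls = unique_markers.calls
    parent = {i: i for i in sig}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    sig_set = set(sig.tolist())
    chrom = tab["chrom"]
    for i in sig:
        if i + 1 in sig_set and chrom.iloc[i] == chrom.iloc[i + 1]:
            union(i, i + 1)
    if len(sig) > 1:
        sub = calls.iloc[:, sig].to_numpy()
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        for a in range(len(sig)):
            for b in range(a + 1, len(sig)):
                if corr[a, b] > ld_r:
                    union(sig[a], sig[b])

    groups: dict[int, list[int]] = {}
    for i in sig:
        groups.setdefault(find(i), []).append(i)

    rows = []
    for members in groups.values():
        members = sorted(members)
        s_arr = np.asarray(s_obs)
        # peak = max S; ties resolved towards the smaller genomic coordinate
        # (map order is chromosome-major, position-minor)
        peak = min(members, key=lambda i: (-s_arr[i], i))
        peak_id = markers[peak]
        peak_chrom = tab.loc[peak_id, "chrom"]
        on_chrom = [i for i in members if tab["chrom"].iloc[i] == peak_chrom]
        effect = np.nan
        if trait_values is not None:
            from .effects import allele_effect
            effect = allele_effect(trait_values, calls[peak_id])
        rows.append({
            "trait": trait,
            "layer": layer,
            "chrom": peak_chrom,
            "start_bp": int(tab["start_bp"].iloc[min(on_chrom)]),
            "end_bp": int(tab["end_bp"].iloc[max(on_chrom)]),
            "peak_marker": peak_id,
            "peak_pos_bp": int(tab.loc[peak_id, "pos_bp"]),
            "peak_s": float(np.asarray(s_obs)[peak]),
            "q_value": float(np.asarray(q_values)[members].min()),
            "effect": effect,
            "n_markers": len(members),
            "members": ",".join(markers[i] for i in members),
        })
    out = pd.DataFrame(rows, columns=QTL_COLUMNS)
    return out.sort_values(["chrom", "start_bp"]).reset_index(drop=True)


def map_traits(
    traits: pd.DataFrame,
    unique_markers: UniqueMarkerSet,
    covariates: pd.DataFrame | None = None,
    config: ForestConfig | None = None,
    layer: str = "trait",
) -> pd.DataFrame:
    """Map every trait column and return the concatenated QTL table.

    ``traits`` is strains x traits; strains with a missing value are
    dropped per trait.  ``covariates`` (strains x k) are appended to the
    marker predictors but never reported.  With ``config.pooled`` (the
    default) q-values come from the linkage-level FDR pooled across the
    mapped traits; otherwise each trait uses its own marker-level
    empirical FDR.
    """
    cfg = config or ForestConfig()
    calls = unique_markers.calls
    strains = calls.index
    if not set(traits.index).issubset(set(strains)):
        raise ValueError("trait strains missing from the genotype matrix")
    cov = covariates.loc[strains].to_numpy() if covariates is not None else None
    n_markers = calls.shape[1]
    per_trait: list[tuple[str, np.ndarray, np.ndarray, pd.Series]] = []
    t0 = time.time()
    for ti, trait in enumerate(traits.columns):
        y_all = traits[trait].reindex(strains)
        keep = y_all.notna().to_numpy()
        y = y_all.to_numpy()[keep]
        X = calls.to_numpy()[keep]
        if cov is not None:
            X = np.hstack([X, cov[keep]])
        obs = forest_importances(y, X, cfg, np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(1, ti))))
        null = permutation_null(y, X, cfg, seed=cfg.seed * 100003 + ti)
        per_trait.append((trait, obs.s[:n_markers], null[:, :n_markers], y_all))
        logger.info("mapped %s (%d/%d) in %.1fs", trait, ti + 1,
                    len(traits.columns), time.time() - t0)
    if cfg.pooled:
        qs = pooled_linkage_fdr(
            [s for _, s, _, _ in per_trait],
            [n for _, _, n, _ in per_trait],
            calls, unique_markers.table["chrom"].to_numpy(), cfg.ld_r)
    else:
        qs = [estimate_fdr(s, n) for _, s, n, _ in per_trait]
    results = []
    for (trait, s_obs, _, y_all), q in zip(per_trait, qs):
        results.append(call_qtls(trait, layer, q, s_obs, unique_markers,
                                 cfg.fdr_threshold, cfg.ld_r, trait_values=y_all))
    results = [r for r in results if len(r)]
    if not results:
        return pd.DataFrame(columns=QTL_COLUMNS)
    return pd.concat(results, ignore_index=True)
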