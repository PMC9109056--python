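"""Genotype call processing for linkage analysis.

Raw biallelic calls from a haploid cross are cleaned in four steps:

1. drop markers with a low call rate (< 70% of strains) or a minor-allele
   frequency below 20% (computed on non-missing calls);
2. exclude markers whose call differs from both immediate flanking
   markers in more than one strain — isolated apparent double
   recombinants, which at typical marker densities almost always denote
   genotyping errors rather than real double crossovers;
3. impute a missing call from its two nearest non-missing neighbours on
   the same chromosome when both lie within 20 kb and carry the same
   parental allele;
4. collapse runs of adjacent markers with identical segregation patterns
   into unique mapping markers, each representing a genomic interval in
   full linkage disequilibrium within the cross.

Population-structure covariates are the top strain-side eigenvectors of
the frequency-normalised genotype matrix (each marker centred by its
allele frequency p and scaled by sqrt(p(1-p)); the haploid analogue of
the Patterson/EIGENSTRAT normalisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeData, MarkerMap

__all__ = [
    "NoMarkersError",
    "ZeroVarianceError",
    "UniqueMarkerSet",
    "StructureCovariates",
    "filter_markers",
    "flag_double_recombinants",
    "impute_missing_genotypes",
    "collapse_markers",
    "structure_eigenvectors",
    "marker_relationship",
    "process_genotypes",
]


class NoMarkersError(ValueError):
    """All markers were removed by a filtering step."""


class ZeroVarianceError(ValueError):
    """A statistic is undefined because a call vector has no variance."""


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_markers(
    geno: GenotypeData,
    min_call_rate: float = 0.70,
    min_maf: float = 0.20,
) -> GenotypeData:
    """Drop markers callable in < ``min_call_rate`` of strains or with
    minor-allele frequency < ``min_maf`` (strict thresholds); order kept."""
    call_rate = geno.call_rate()
    maf = geno.minor_allele_freq()
    keep = (call_rate >= min_call_rate) & (maf >= min_maf)
    if not keep.any():
        raise NoMarkersError("no markers survive call-rate/MAF filtering")
    kept = keep[keep].index.tolist()
    table = geno.markers.table
    new_map = MarkerMap(table[table["marker"].isin(kept)])
    return GenotypeData(geno.calls[kept], new_map)


def flag_double_recombinants(geno: GenotypeData, max_strains: int = 1) -> set[str]:
    """Markers differing from both immediate flanking markers in more than
    ``max_strains`` strains (likely call errors).  Chromosome ends and
    chromosomes with fewer than three markers cannot be flagged."""
    flagged: set[str] = set()
    tab = geno.markers.table
    for chrom in geno.markers.chromosomes():
        ids = tab.loc[tab["chrom"] == chrom, "marker"].tolist()
        if len(ids) < 3:
            continue
        block = geno.calls[ids].to_numpy()
        mid, left, right = block[:, 1:-1], block[:, :-2], block[:, 2:]
        ok = ~np.isnan(mid) & ~np.isnan(left) & ~np.isnan(right)
        mism = ok & (mid != left) & (mid != right)
        counts = mism.sum(axis=0)
        for j, c in enumerate(counts):
            if c > max_strains:
                flagged.add(ids[j + 1])
    return flagged


def drop_markers(geno: GenotypeData, markers: set[str]) -> GenotypeData:
    keep = [m for m in geno.markers.markers if m not in markers]
    if not keep:
        raise NoMarkersError("no markers left after dropping flagged markers")
    tab = geno.markers.table
    return GenotypeData(geno.calls[keep],
                        MarkerMap(tab[tab["marker"].isin(keep)]))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing_genotypes(geno: GenotypeData, max_dist_bp: int = 20_000) -> GenotypeData:
    """Fill a missing call with the shared parental allele of its nearest
    non-missing neighbours when both are within ``max_dist_bp`` and agree.

    Neighbours are the closest non-missing markers in bp on the same
    chromosome for that strain.  Calls whose neighbours disagree, are too
    far, or do not exist stay missing.
    """
    tab = geno.markers.table
    calls = geno.calls.to_numpy(copy=True)
    col_of = {m: i for i, m in enumerate(geno.markers.markers)}
    for chrom in geno.markers.chromosomes():
        sub = tab[tab["chrom"] == chrom]
        cols = np.array([col_of[m] for m in sub["marker"]])
        pos = sub["pos_bp"].to_numpy()
        block = calls[:, cols]
        nan_rows, nan_cols = np.nonzero(np.isnan(block))
        for s, j in zip(nan_rows, nan_cols):
            row = block[s]
            left = right = None
            for k in range(j - 1, -1, -1):
                if not np.isnan(row[k]):
                    left = k
                    break
            for k in range(j + 1, len(row)):
                if not np.isnan(row[k]):
                    right = k
                    break
            if left is None or right is None:
                continue
            if pos[j] - pos[left] > max_dist_bp or pos[right] - pos[j] > max_dist_bp:
                continue
            if row[left] == row[right]:
                calls[s, cols[j]] = row[left]
    out = pd.DataFrame(calls, index=geno.calls.index, columns=geno.calls.columns)
    return GenotypeData(out, geno.markers)


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

@dataclass
class UniqueMarkerSet:
    """Collapsed unique mapping markers.

    ``calls``: strains x unique markers; ``table``: per unique marker the
    chromosome, spanned interval, representative position (interval
    midpoint) and member marker ids; ``member_of``: member -> unique id.
    """

    calls: pd.DataFrame
    table: pd.DataFrame  # unique_marker, chrom, start_bp, end_bp, pos_bp, members
    member_of: pd.Series

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    def marker_map(self) -> MarkerMap:
        """Representative-position map for downstream genomic placement."""
        t = self.table.rename(columns={"unique_marker": "marker"})
        return MarkerMap(t[["marker", "chrom", "pos_bp"]])


def collapse_markers(geno: GenotypeData) -> UniqueMarkerSet:
    """Merge runs of adjacent markers with identical strain-call vectors.

    Missing calls are treated as a distinct pattern symbol, so two markers
    only merge when they agree on every strain including missingness.
    """
    tab = geno.markers.table
    rows = []
    call_cols = {}
    member_of = {}
    for chrom in geno.markers.chromosomes():
        sub = tab[tab["chrom"] == chrom]
        ids = sub["marker"].tolist()
        pos = sub["pos_bp"].to_numpy()
        block = geno.calls[ids].to_numpy()
        start = 0
        uid = 0
        for j in range(1, len(ids) + 1):
            new_run = j == len(ids) or not _same_pattern(block[:, start], block[:, j])
            if new_run:
                members = ids[start:j]
                name = f"{chrom}_u{uid:04d}"
                uid += 1
                lo, hi = int(pos[start]), int(pos[j - 1])
                rows.append((name, chrom, lo, hi, (lo + hi) // 2, ",".join(members)))
                call_cols[name] = block[:, start]
                for m in members:
                    member_of[m] = name
                start = j
    table = pd.DataFrame(
        rows, columns=["unique_marker", "chrom", "start_bp", "end_bp", "pos_bp", "members"])
    calls = pd.DataFrame(call_cols, index=geno.calls.index)
    return UniqueMarkerSet(calls, table, pd.Series(member_of, name="unique_marker"))


def _same_pattern(a: np.ndarray, b: np.ndarray) -> bool:
    na_a, na_b = np.isnan(a), np.isnan(b)
    if not np.array_equal(na_a, na_b):
        return False
    return bool(np.array_equal(a[~na_a], b[~na_b]))


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------

@dataclass
class StructureCovariates:
    """Top strain-side eigenvectors of the normalised genotype matrix."""

    vectors: pd.DataFrame      # strains x k, orthonormal columns
    eigenvalues: np.ndarray    # length k, descending
    variance_fraction: float   # cumulative fraction explained by the k axes


def structure_eigenvectors(calls: pd.DataFrame, k: int = 7) -> StructureCovariates:
    """SVD of the frequency-normalised strains x markers matrix.

    Each marker column is centred by its allele frequency p and scaled by
    sqrt(p(1-p)) (haploid convention).  Monomorphic markers are rejected;
    requesting more axes than the matrix rank returns rank-many with a
    warning.
    """
    X = calls.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("structure eigenvectors require NA-free calls")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 strains and 2 markers")
    p = X.mean(axis=0)
    if np.any((p == 0.0) | (p == 1.0)):
        raise ZeroVarianceError("monomorphic markers present; filter first")
    Z = (X - p) / np.sqrt(p * (1.0 - p))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    ev = s ** 2
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        warnings.warn(f"requested {k} axes but rank is {rank}; returning {rank}")
        k = rank
    if k < 1:
        raise ValueError("k must be >= 1")
    vectors = pd.DataFrame(
        U[:, :k], index=calls.index, columns=[f"PC{i + 1}" for i in range(k)])
    return StructureCovariates(vectors, ev[:k], float(ev[:k].sum() / ev.sum()))


# ---------------------------------------------------------------------------
# pairwise marker relationships
# ---------------------------------------------------------------------------

def marker_relationship(g_a: np.ndarray, g_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and genetic distance of two 0/1 call vectors.

    cM = (number of recombinant strains / n) * 100, counting every strain
    whose alleles differ between the two markers.  Parental strains must
    already be excluded from the vectors.
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need at least two shared non-missing calls")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ZeroVarianceError("correlation undefined for a fixed marker")
    r = float(np.corrcoef(a, b)[0, 1])
    cm = float((a != b).mean() * 100.0)
    return r, cm


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def process_genotypes(
    geno: GenotypeData,
    min_call_rate: float = 0.70,
    min_maf: float = 0.20,
    impute_dist_bp: int = 20_000,
    drop_incomplete: bool = True,
) -> UniqueMarkerSet:
    """filter -> flag double recombinants -> impute -> collapse.

    With ``drop_incomplete`` markers still carrying missing calls after
    imputation are removed so the collapsed matrix is NA-free, as required
    by the mapper.
    """
    g = filter_markers(geno, min_call_rate, min_maf)
    flagged = flag_double_recombinants(g)
    if flagged:
        g = drop_markers(g, flagged)
    g = impute_missing_genotypes(g, impute_dist_bp)
    if drop_incomplete:
        complete = g.calls.columns[g.calls.notna().all(axis=0)].tolist()
        if not complete:
            raise NoMarkersError("no complete markers after imputation")
        tab = g.markers.table
        g = GenotypeData(g.calls[complete],
                         MarkerMap(tab[tab["marker"].isin(complete)]))
    return collapse_markers(g)
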