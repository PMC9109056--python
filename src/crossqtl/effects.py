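"""QTL characterisation: effect sizes, transmission classes, local/distant
calls, hotspot detection, and sequence-context annotation.

Effect sizes are allele log2 fold changes with a fixed sign convention,
E = mean(trait | BY allele) - mean(trait | RM allele).  The transmission
of a transcript-level effect E_e to the protein level E_p is summarised
by the signed difference

    Delta_ep = sign(E_e) * (E_e - E_p)

classified with a 0.15 log2 threshold: |Delta_ep| within the threshold is
"similar", Delta_ep above +0.15 is "buffered" (the protein responds less
than the transcript), below -0.15 "enhanced".  Protein-layer QTLs without
any transcript-level counterpart for the same gene are "protein_only".

Hotspots are genomic bins holding more QTL linkages than a Poisson null
with mean total-linkages/bins would allow at tail probability alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import UniqueMarkerSet, ZeroVarianceError, marker_relationship

__all__ = [
    "allele_effect",
    "classify_transmission",
    "classify_transmission_table",
    "annotate_protein_only",
    "classify_local_distant",
    "poisson_threshold",
    "detect_hotspots",
    "transmission_slope",
    "missense_distance",
    "GeneModel",
    "count_region_snps",
]

TRANSMISSION_THRESHOLD = 0.15


def allele_effect(trait: pd.Series | np.ndarray, genotype: pd.Series | np.ndarray) -> float:
    """Allele log2 fold change at a marker: mean(BY) - mean(RM).

    Genotype coding: 0 = BY, 1 = RM.  Missing values are dropped pairwise;
    both allele groups must be non-empty.
    """
    t = np.asarray(trait, dtype=float)
    g = np.asarray(genotype, dtype=float)
    ok = ~np.isnan(t) & ~np.isnan(g)
    t, g = t[ok], g[ok]
    by, rm = t[g == 0], t[g == 1]
    if len(by) == 0 or len(rm) == 0:
        raise ValueError("both allele groups must be non-empty")
    return float(by.mean() - rm.mean())


def classify_transmission(e_e: float, e_p: float,
                          threshold: float = TRANSMISSION_THRESHOLD) -> str:
    """Class of a transcript-to-protein effect pair.

    Delta_ep = sign(E_e) * (E_e - E_p); buffered iff Delta_ep > threshold,
    enhanced iff Delta_ep < -threshold, similar otherwise (the exact
    boundary counts as similar).  E_e = 0 is unclassifiable.
    """
    if e_e == 0:
        raise ValueError("transmission class undefined for E_e = 0")
    delta = (e_e / abs(e_e)) * (e_e - e_p)
    if delta > threshold:
        return "buffered"
    if delta < -threshold:
        return "enhanced"
    return "similar"


def classify_transmission_table(pairs: pd.DataFrame,
                                threshold: float = TRANSMISSION_THRESHOLD) -> pd.Series:
    """Vectorised classification; rows with E_e == 0 become 'unclassified'."""
    out = []
    for e_e, e_p in zip(pairs["e_transcript"], pairs["e_protein"]):
        if e_e == 0 or not np.isfinite(e_e) or not np.isfinite(e_p):
            out.append("unclassified")
        else:
            out.append(classify_transmission(e_e, e_p, threshold))
    return pd.Series(out, index=pairs.index, name="class")


def _linked(members_a: list[str], members_b: list[str],
            calls: pd.DataFrame, r_threshold: float) -> bool:
    """Do two marker sets overlap or contain a pair with r > threshold?"""
    if set(members_a) & set(members_b):
        return True
    for a in members_a:
        va = calls[a].to_numpy()
        for b in members_b:
            try:
                r, _ = marker_relationship(va, calls[b].to_numpy())
            except ZeroVarianceError:
                continue
            if r > r_threshold:
                return True
    return False


def annotate_protein_only(
    pt_qtls: pd.DataFrame,
    e_qtls: pd.DataFrame,
    unique_markers: UniqueMarkerSet,
    gene_of: pd.Series,
    r_threshold: float = 0.8,
) -> pd.Series:
    """Flag post-transcriptional QTLs lacking any transcript counterpart.

    A ptQTL is protein_only iff no eQTL for the same gene shares a member
    marker with it or is linked to it at r > ``r_threshold``.  ``gene_of``
    maps trait id -> gene id for both tables.
    """
    calls = unique_markers.calls
    flags = []
    for _, row in pt_qtls.iterrows():
        gene = gene_of.get(row["trait"])
        mine = row["members"].split(",")
        is_only = True
        for _, erow in e_qtls.iterrows():
            if gene_of.get(erow["trait"]) != gene:
                continue
            if _linked(mine, erow["members"].split(","), calls, r_threshold):
                is_only = False
                break
        flags.append(is_only)
    return pd.Series(flags, index=pt_qtls.index, name="protein_only")


def classify_local_distant(
    qtl_members: list[str],
    gene_chrom: str,
    gene_pos: int,
    unique_markers: UniqueMarkerSet,
    r_threshold: float = 0.8,
) -> bool:
    """True (local) iff any QTL member correlates at >= ``r_threshold``
    with a marker directly flanking the target gene.

    Flanking markers are the nearest unique markers up- and downstream of
    the gene midpoint on its chromosome; a gene beyond the terminal marker
    uses its single flank.
    """
    tab = unique_markers.table
    sub = tab[tab["chrom"] == gene_chrom]
    if sub.empty:
        return False
    pos = sub["pos_bp"].to_numpy()
    ids = sub["unique_marker"].to_numpy()
    up = ids[pos <= gene_pos][-1:] if (pos <= gene_pos).any() else np.array([], dtype=object)
    down = ids[pos > gene_pos][:1] if (pos > gene_pos).any() else np.array([], dtype=object)
    flanks = list(up) + list(down)
    calls = unique_markers.calls
    for m in qtl_members:
        for f in flanks:
            if m == f:
                return True
            try:
                r, _ = marker_relationship(calls[m].to_numpy(), calls[f].to_numpy())
            except ZeroVarianceError:
                continue
            if r >= r_threshold:
                return True
    return False


def poisson_threshold(lam: float, alpha: float = 0.01) -> int:
    """Smallest integer k with Poisson(lam) CDF P(X <= k) >= 1 - alpha.

    Computed by exact term summation; bins with a count strictly greater
    than k are hotspot candidates.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if lam == 0:
        return 0
    term = math.exp(-lam)
    cdf = term
    k = 0
    target = 1.0 - alpha
    while cdf < target:
        k += 1
        term *= lam / k
        cdf += term
        if k > 10_000_000:  # pragma: no cover - guard against pathological lam
            raise OverflowError("lambda too large for exact summation")
    return k


def _genome_bins(chrom_lengths: dict[str, int], bin_bp: int) -> pd.DataFrame:
    """Half-open 40-kb-style bins; the final partial bin is merged into its
    predecessor, so terminal bins can be bigger."""
    rows = []
    for chrom, length in chrom_lengths.items():
        n_full = max(1, length // bin_bp)
        starts = [1 + i * bin_bp for i in range(n_full)]
        ends = [s + bin_bp - 1 for s in starts]
        ends[-1] = length  # absorb the remainder
        for s, e in zip(starts, ends):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp"])


def detect_hotspots(
    qtls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_bp: int = 40_000,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin QTL counts, Poisson thresholds and merged hotspot intervals.

    QTLs are assigned to bins by their peak marker position, separately
    per layer; the per-layer null mean is total linkages / total bins.
    Returns ``(bins, hotspots)``: the per-bin table with per-layer counts,
    thresholds and flags, and merged intervals of consecutive flagged bins
    on the same chromosome.
    """
    bins = _genome_bins(chrom_lengths, bin_bp)
    n_bins = len(bins)
    layers = sorted(qtls["layer"].unique()) if len(qtls) else []
    hot_rows = []
    for layer in layers:
        sub = qtls[qtls["layer"] == layer]
        lam = len(sub) / n_bins
        k = poisson_threshold(lam, alpha)
        counts = np.zeros(n_bins, dtype=int)
        for _, row in sub.iterrows():
            sel = ((bins["chrom"] == row["chrom"])
                   & (bins["start_bp"] <= row["peak_pos_bp"])
                   & (bins["end_bp"] >= row["peak_pos_bp"]))
            idx = np.flatnonzero(sel.to_numpy())
            if len(idx):
                counts[idx[0]] += 1
        bins[f"count_{layer}"] = counts
        bins[f"threshold_{layer}"] = k
        bins[f"hotspot_{layer}"] = counts > k
        # merge consecutive flagged bins per chromosome
        flagged = bins[bins[f"hotspot_{layer}"]]
        for chrom, grp in flagged.groupby("chrom", sort=False):
            idxs = grp.index.to_numpy()
            run_start = idxs[0]
            prev = idxs[0]
            for i in list(idxs[1:]) + [None]:
                if i is None or i != prev + 1:
                    hot_rows.append((layer, chrom,
                                     int(bins.loc[run_start, "start_bp"]),
                                     int(bins.loc[prev, "end_bp"]),
                                     int(bins.loc[run_start:prev, f"count_{layer}"].sum())))
                    run_start = i
                prev = i
    hotspots = pd.DataFrame(
        hot_rows, columns=["layer", "chrom", "start_bp", "end_bp", "n_qtls"])
    return bins, hotspots


def transmission_slope(pairs: pd.DataFrame, subset: str | None = None) -> tuple[float, float]:
    """OLS slope (and its SE) of protein effects on transcript effects.

    ``pairs`` needs columns e_transcript, e_protein and, when ``subset``
    is given, a boolean ``local`` column ('local' / 'distant' subsets).
    """
    df = pairs
    if subset is not None:
        if subset not in ("local", "distant"):
            raise ValueError("subset must be 'local' or 'distant'")
        df = pairs[pairs["local"] == (subset == "local")]
    if len(df) < 3:
        raise ValueError("need at least 3 effect pairs")
    x = df["e_transcript"].to_numpy(dtype=float)
    y = df["e_protein"].to_numpy(dtype=float)
    if x.std() == 0.0:
        raise ZeroVarianceError("degenerate transcript effects")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.stderr)


def missense_distance(site_position: int, polymorphic_positions) -> int:
    """Distance (in residues) from a phosphosite to the nearest
    polymorphic amino acid of the same protein."""
    poly = list(polymorphic_positions)
    if not poly:
        raise ValueError("no polymorphic positions given")
    return int(min(abs(int(site_position) - int(p)) for p in poly))


@dataclass
class GeneModel:
    """Gene structure for SNP-context counting (1-based inclusive bp).

    Genes carrying insertions/deletions are excluded from SNP-context
    analysis via ``has_indel``.  ``missense_positions`` lists CDS bp
    positions whose SNPs change the amino acid.
    """

    gene: str
    chrom: str
    strand: str            # '+' or '-'
    cds: tuple[int, int]
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None
    upstream_bp: int = 2000
    downstream_bp: int = 2000
    protein_length: int | None = None
    missense_positions: frozenset[int] = field(default_factory=frozenset)
    has_indel: bool = False

    def regions(self) -> dict[str, tuple[int, int]]:
        """Region intervals; up/downstream windows start at the outer UTR
        borders (or the CDS when a UTR is absent) and span 2 kb each."""
        up_anchor = self.utr5[0] if self.utr5 else self.cds[0]
        down_anchor = self.utr3[1] if self.utr3 else self.cds[1]
        if self.strand == "-":
            up_anchor = self.utr5[1] if self.utr5 else self.cds[1]
            down_anchor = self.utr3[0] if self.utr3 else self.cds[0]
            regions = {
                "upstream": (up_anchor + 1, up_anchor + self.upstream_bp),
                "downstream": (max(1, down_anchor - self.downstream_bp), down_anchor - 1),
            }
        else:
            regions = {
                "upstream": (max(1, up_anchor - self.upstream_bp), up_anchor - 1),
                "downstream": (down_anchor + 1, down_anchor + self.downstream_bp),
            }
        if self.utr5:
            regions["utr5"] = self.utr5
        if self.utr3:
            regions["utr3"] = self.utr3
        regions["cds"] = self.cds
        return regions

    def codon_index(self, pos: int) -> int:
        """0-based codon number of a CDS bp position, strand aware."""
        lo, hi = self.cds
        if not lo <= pos <= hi:
            raise ValueError("position outside the CDS")
        offset = pos - lo if self.strand != "-" else hi - pos
        return offset // 3


def count_region_snps(gene: GeneModel, snp_positions) -> dict[str, int]:
    """SNP counts per gene region plus amino-acid changes.

    Interval membership is 1-based inclusive; multiple SNPs in the same
    codon count as a single amino-acid change.  Indel-flagged genes are
    rejected.
    """
    if gene.has_indel:
        raise ValueError("genes with indels are excluded from SNP-context analysis")
    snps = sorted(int(p) for p in snp_positions)
    counts = {"upstream": 0, "utr5": 0, "cds": 0, "utr3": 0,
              "downstream": 0, "aa_changes": 0}
    regions = gene.regions()
    codons = set()
    for pos in snps:
        for name, (lo, hi) in regions.items():
            if lo <= pos <= hi:
                counts[name] += 1
        if pos in gene.missense_positions:
            codons.add(gene.codon_index(pos))
    counts["aa_changes"] = len(codons)
    return counts
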