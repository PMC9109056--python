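"""Synthetic biparental segregant panel with known ground truth.

Emulates the data structure of a haploid two-parent yeast cross profiled on
several molecular layers (transcripts, proteins, phosphopeptides) plus
physiological traits.  Genotypes are abstract biallelic calls (0 = first
parent, "BY"; 1 = second parent, "RM") generated marker-by-marker as a
two-state Markov chain along each chromosome, with the recombination
fraction between adjacent markers given by the Haldane map function

    c = 0.5 * (1 - exp(-2 d / 100)),   d in centimorgan,

where d is derived from physical distance through a configurable
cM-per-kb rate.  Molecular layers are built hierarchically:

    transcript  t  = sum_k beta_k x_k            + eps_t
    protein     p  = alpha * t + sum_k beta'_k x_k  + eps_p
    phospho     ph = gamma * p + sum_k beta''_k x_k + eps_ph

so that transcript effects are partially transmitted to proteins (and may
be buffered, i.e. cancelled, or enhanced at the protein layer), and
phosphopeptides combine protein-abundance-driven and direct genetic
effects.  Every nonzero coefficient, the per-trait broad-sense
heritability implied by the replicate design, and the mediation structure
of physiological traits are recorded in a :class:`CrossTruth` object so
that downstream estimators can be validated against known truth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each sub-step draws from an
independent, reproducible stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeData",
    "SimulationConfig",
    "CrossTruth",
    "make_marker_map",
    "simulate_genotypes",
    "simulate_trait_layers",
    "make_sample_design",
    "expand_to_samples",
    "inject_missingness",
    "simulate_physiology",
    "simulate_panel",
]

#: residue-type frequencies used for phosphosite annotations (S, T, Y)
PHOSPHOSITE_RESIDUE_PROBS = (0.762, 0.222, 0.016)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for sub-step ``key`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

class MarkerMap:
    """Ordered genomic marker positions.

    Wraps a DataFrame with columns ``marker``, ``chrom``, ``pos_bp`` (1-based)
    and validates that positions are strictly increasing within each
    chromosome and marker ids are unique.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "pos_bp"}
        if not required.issubset(table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        table = table.reset_index(drop=True)
        if table["marker"].duplicated().any():
            raise ValueError("marker ids must be unique")
        if (table["pos_bp"] < 1).any():
            raise ValueError("positions must be >= 1")
        for _, grp in table.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing or grp["pos_bp"].duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


def make_marker_map(
    chrom_lengths: dict[str, int],
    spacing_bp: int = 10_000,
    first_bp: int = 5_000,
) -> MarkerMap:
    """Evenly spaced marker grid over the given chromosome lengths."""
    rows = []
    for chrom, length in chrom_lengths.items():
        positions = np.arange(first_bp, length + 1, spacing_bp)
        for i, pos in enumerate(positions):
            rows.append((f"{chrom}_m{i:04d}", chrom, int(pos)))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp"]))


@dataclass
class GenotypeData:
    """Strain-by-marker biallelic calls (0 = BY, 1 = RM, NaN = missing)."""

    calls: pd.DataFrame  # index: strains, columns: marker ids, float 0/1/NaN
    markers: MarkerMap

    def __post_init__(self):
        if list(self.calls.columns) != self.markers.markers:
            raise ValueError("call columns must match marker map order")

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    def minor_allele_freq(self) -> pd.Series:
        """Per-marker minor-allele frequency on non-missing calls."""
        freq = self.calls.mean(axis=0, skipna=True)
        return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1)

    def call_rate(self) -> pd.Series:
        return self.calls.notna().mean(axis=0)


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class HotspotSpec:
    """A master-regulator locus affecting a fraction of one layer's traits."""

    marker: str
    target_fraction: float = 0.25
    layer: str = "transcript"
    effect_size: float = 1.0


@dataclass
class MediationSpec:
    """One genotype -> mediator -> outcome triple (path a, b, direct c')."""

    marker: str
    mediator_layer: str
    mediator_trait: str | None  # None: pick/create one
    a: float = 1.0
    b: float = 0.5
    c_prime: float = 0.0


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic segregant panel.

    The defaults emulate the profiled cross at desk scale: 110 recombinant
    strains, a marker grid collapsing to roughly 300 unique mapping markers,
    three molecular layers on log2 scale, a replicate design with six
    strains measured in triplicate, and small additive batch effects.
    """

    n_strains: int = 110
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{r}": 760_000 for r in ("I", "II", "III", "IV")}
    )
    marker_spacing_bp: int = 10_000
    cm_per_kb: float = 0.4

    # layer sizes
    n_transcripts: int = 200
    n_proteins: int = 120
    n_phosphoproteins: int = 60
    peptides_per_protein: tuple[int, int] = (1, 3)

    # genetic architecture
    frac_transcript_null: float = 0.2
    n_qtl_per_transcript: int = 1
    beta_range: tuple[float, float] = (0.5, 1.5)
    frac_buffered: float = 0.15
    frac_enhanced: float = 0.10
    frac_protein_only: float = 0.10
    frac_phospho_direct: float = 0.25
    alpha_transmission: float = 0.7  # transcript -> protein
    gamma_transmission: float = 0.7  # protein -> phospho
    hotspots: list[HotspotSpec] = field(default_factory=list)

    # noise (log2 units, strain level)
    sigma_transcript: float = 0.5
    sigma_protein: float = 0.4
    sigma_phospho: float = 0.5

    # replicate / batch design
    n_replicated_strains: int = 6
    replicates_per_strain: int = 3
    sigma_replicate: float = 0.4
    n_batches: int = 3
    sigma_batch: float = 0.3

    # physiology
    n_physio: int = 6
    sigma_physio: float = 0.5
    mediations: list[MediationSpec] = field(default_factory=list)

    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_transcript", "sigma_protein", "sigma_phospho",
                     "sigma_replicate", "sigma_batch", "sigma_physio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicated_strains < 2 or self.replicates_per_strain < 3:
            raise ValueError("replicate design needs >= 2 strains with >= 3 replicates")


@dataclass
class CrossTruth:
    """Ground truth of a simulated cross.

    ``links``: one row per nonzero genetic coefficient
    (trait, layer, marker, effect); ``heritability``: realized broad-sense
    H2 per trait, Var(strain values)/(Var(strain values)+sigma_rep^2);
    ``mediation``: path coefficients of the physiological triples.
    """

    links: pd.DataFrame
    heritability: pd.DataFrame
    mediation: pd.DataFrame

    def causal_markers(self, trait: str) -> set[str]:
        sub = self.links[self.links["trait"] == trait]
        return set(sub["marker"])


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def haldane_recomb_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a genetic distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_genotypes(
    markers: MarkerMap,
    n_strains: int,
    seed: int,
    cm_per_kb: float = 0.4,
    strain_prefix: str = "seg",
) -> GenotypeData:
    """Simulate haploid segregant genotypes along the marker map.

    Each chromosome is an independent two-state Markov chain per strain:
    the first marker's allele is Bernoulli(1/2) and the transition
    probability between adjacent markers is the Haldane recombination
    fraction for their distance (bp converted at ``cm_per_kb``).
    """
    if n_strains < 2:
        raise ValueError("need at least two strains")
    rng = _rng(seed, 0)
    tab = markers.table
    n_m = len(tab)
    calls = np.empty((n_strains, n_m), dtype=float)
    col = 0
    for chrom in markers.chromosomes():
        pos = tab.loc[tab["chrom"] == chrom, "pos_bp"].to_numpy()
        d_cm = np.diff(pos) / 1000.0 * cm_per_kb
        c = haldane_recomb_fraction(d_cm)  # shape (m-1,)
        m = len(pos)
        block = np.empty((n_strains, m))
        block[:, 0] = rng.integers(0, 2, size=n_strains)
        if m > 1:
            flips = rng.random((n_strains, m - 1)) < c[None, :]
            block[:, 1:] = flips
            np.cumsum(block, axis=1, out=block)
            block %= 2
        calls[:, col:col + m] = block
        col += m
    strains = [f"{strain_prefix}{i:03d}" for i in range(n_strains)]
    df = pd.DataFrame(calls, index=strains, columns=markers.markers)
    return GenotypeData(df, markers)


# ---------------------------------------------------------------------------
# trait layers
# ---------------------------------------------------------------------------

def _draw_beta(rng: np.random.Generator, lo: float, hi: float) -> float:
    return rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)


def simulate_trait_layers(
    geno: GenotypeData,
    config: SimulationConfig,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, CrossTruth]:
    """Generate strain-level transcript, protein and phospho layers.

    Returns ``(layers, annotations, truth)`` where ``layers`` maps layer
    name to a strains x traits DataFrame (log2 scale), ``annotations``
    carries per-trait gene ids, genomic positions, peptide-to-protein
    mappings and phosphosite residues, and ``truth`` records all causal
    coefficients plus realized heritability.
    """
    cfg = config
    rng_arch = _rng(seed, 1)
    rng_noise = _rng(seed, 2)
    rng_annot = _rng(seed, 3)

    X = geno.calls.to_numpy()
    if np.isnan(X).any():
        raise ValueError("trait simulation requires NA-free genotypes")
    strains = geno.strains
    marker_ids = geno.markers.markers
    marker_index = {m: i for i, m in enumerate(marker_ids)}
    tab = geno.markers.table
    n = len(strains)

    for hs in cfg.hotspots:
        if hs.marker not in marker_index:
            raise ValueError(f"unknown hotspot locus {hs.marker!r}")

    links: list[tuple[str, str, str, float]] = []
    annot_rows: list[dict] = []

    # -- transcripts -----------------------------------------------------
    n_tx = cfg.n_transcripts
    tx_ids = [f"gene{i:04d}" for i in range(n_tx)]
    # gene genomic positions: uniform over the marker map
    gene_rows = rng_annot.integers(0, len(tab), size=n_tx)
    gene_chrom = tab["chrom"].to_numpy()[gene_rows]
    gene_pos = tab["pos_bp"].to_numpy()[gene_rows] + rng_annot.integers(-4000, 4000, size=n_tx)
    gene_pos = np.maximum(gene_pos, 1)

    tx_effects: dict[str, dict[int, float]] = {t: {} for t in tx_ids}
    n_null = int(round(cfg.frac_transcript_null * n_tx))
    null_set = set(rng_arch.choice(n_tx, size=n_null, replace=False))
    for i, t in enumerate(tx_ids):
        if i in null_set:
            continue
        for _ in range(cfg.n_qtl_per_transcript):
            j = int(rng_arch.integers(0, len(marker_ids)))
            beta = _draw_beta(rng_arch, *cfg.beta_range)
            tx_effects[t][j] = tx_effects[t].get(j, 0.0) + beta

    # hotspot loci targeting a fraction of transcript traits
    for hs in cfg.hotspots:
        if hs.layer != "transcript":
            continue
        j = marker_index[hs.marker]
        n_targets = int(round(hs.target_fraction * n_tx))
        targets = rng_arch.choice(n_tx, size=n_targets, replace=False)
        for ti in targets:
            t = tx_ids[ti]
            beta = rng_arch.choice([-1.0, 1.0]) * hs.effect_size
            tx_effects[t][j] = tx_effects[t].get(j, 0.0) + beta

    T = np.zeros((n, n_tx))
    for i, t in enumerate(tx_ids):
        for j, beta in tx_effects[t].items():
            T[:, i] += beta * X[:, j]
            links.append((t, "transcript", marker_ids[j], beta))
    T += rng_noise.normal(0.0, cfg.sigma_transcript, size=T.shape)

    for i, t in enumerate(tx_ids):
        annot_rows.append({
            "trait": t, "layer": "transcript", "gene": t,
            "chrom": gene_chrom[i], "pos_bp": int(gene_pos[i]),
            "protein_of_origin": "", "residue": "", "site_pos": np.nan,
        })

    # -- proteins --------------------------------------------------------
    n_pr = min(cfg.n_proteins, n_tx)
    pr_ids = [f"prot_{tx_ids[i]}" for i in range(n_pr)]
    classes = _assign_protein_classes(rng_arch, n_pr, cfg)
    P = np.zeros((n, n_pr))
    pr_effects: dict[str, dict[int, float]] = {p: {} for p in pr_ids}
    for i, p in enumerate(pr_ids):
        gene_i = i  # protein i originates from transcript i
        P[:, i] = cfg.alpha_transmission * T[:, gene_i]
        cls = classes[i]
        if cls == "buffered":
            # cancel the transmitted genetic signal marker by marker
            for j, beta in tx_effects[tx_ids[gene_i]].items():
                pr_effects[p][j] = -cfg.alpha_transmission * beta
        elif cls == "enhanced":
            for j, beta in tx_effects[tx_ids[gene_i]].items():
                pr_effects[p][j] = 0.5 * np.sign(beta) * abs(beta)
        elif cls == "protein_only":
            j = int(rng_arch.integers(0, len(marker_ids)))
            pr_effects[p][j] = _draw_beta(rng_arch, *cfg.beta_range)
        for j, bprime in pr_effects[p].items():
            P[:, i] += bprime * X[:, j]
            links.append((p, "protein", marker_ids[j], bprime))
    P += rng_noise.normal(0.0, cfg.sigma_protein, size=P.shape)

    for i, p in enumerate(pr_ids):
        annot_rows.append({
            "trait": p, "layer": "protein", "gene": tx_ids[i],
            "chrom": gene_chrom[i], "pos_bp": int(gene_pos[i]),
            "protein_of_origin": "", "residue": "", "site_pos": np.nan,
        })

    # -- phosphopeptides -------------------------------------------------
    n_php = min(cfg.n_phosphoproteins, n_pr)
    pep_ids: list[str] = []
    pep_protein: list[int] = []
    for i in range(n_php):
        k = int(rng_annot.integers(cfg.peptides_per_protein[0],
                                   cfg.peptides_per_protein[1] + 1))
        for pe in range(k):
            pep_ids.append(f"pep_{tx_ids[i]}_{pe}")
            pep_protein.append(i)
    PH = np.zeros((n, len(pep_ids)))
    ph_effects: dict[str, dict[int, float]] = {pp: {} for pp in pep_ids}
    n_direct = int(round(cfg.frac_phospho_direct * len(pep_ids)))
    direct_set = set(rng_arch.choice(len(pep_ids), size=n_direct, replace=False))
    for i, pp in enumerate(pep_ids):
        PH[:, i] = cfg.gamma_transmission * P[:, pep_protein[i]]
        if i in direct_set:
            j = int(rng_arch.integers(0, len(marker_ids)))
            ph_effects[pp][j] = _draw_beta(rng_arch, *cfg.beta_range)
        for j, bpp in ph_effects[pp].items():
            PH[:, i] += bpp * X[:, j]
            links.append((pp, "phospho", marker_ids[j], bpp))
    PH += rng_noise.normal(0.0, cfg.sigma_phospho, size=PH.shape)

    residues = rng_annot.choice(["S", "T", "Y"], size=len(pep_ids),
                                p=PHOSPHOSITE_RESIDUE_PROBS)
    for i, pp in enumerate(pep_ids):
        gi = pep_protein[i]
        annot_rows.append({
            "trait": pp, "layer": "phospho", "gene": tx_ids[gi],
            "chrom": gene_chrom[gi], "pos_bp": int(gene_pos[gi]),
            "protein_of_origin": pr_ids[gi],
            "residue": str(residues[i]),
            "site_pos": int(rng_annot.integers(1, 500)),
        })

    layers = {
        "transcript": pd.DataFrame(T, index=strains, columns=tx_ids),
        "protein": pd.DataFrame(P, index=strains, columns=pr_ids),
        "phospho": pd.DataFrame(PH, index=strains, columns=pep_ids),
    }
    annotations = pd.DataFrame(annot_rows)

    link_df = pd.DataFrame(links, columns=["trait", "layer", "marker", "effect"])
    h2_rows = []
    for layer, df in layers.items():
        v = df.to_numpy().var(axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            h2 = v / (v + cfg.sigma_replicate ** 2)
        for trait, h in zip(df.columns, h2):
            h2_rows.append((trait, layer, float(h)))
    h2_df = pd.DataFrame(h2_rows, columns=["trait", "layer", "h2_true"])
    truth = CrossTruth(link_df, h2_df, pd.DataFrame(
        columns=["physio_trait", "marker", "mediator", "a", "b", "c_prime"]))
    return layers, annotations, truth


def _assign_protein_classes(rng, n_pr: int, cfg: SimulationConfig) -> list[str]:
    n_buf = int(round(cfg.frac_buffered * n_pr))
    n_enh = int(round(cfg.frac_enhanced * n_pr))
    n_po = int(round(cfg.frac_protein_only * n_pr))
    labels = (["buffered"] * n_buf + ["enhanced"] * n_enh +
              ["protein_only"] * n_po)
    labels += ["similar"] * (n_pr - len(labels))
    labels = np.array(labels[:n_pr])
    rng.shuffle(labels)
    return labels.tolist()


# ---------------------------------------------------------------------------
# samples, replicates, batches
# ---------------------------------------------------------------------------

def make_sample_design(
    strains: list[str],
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Replicate/batch layout shared by all molecular layers.

    The first ``n_replicated_strains`` strains get
    ``replicates_per_strain`` samples each; every other strain gets one.
    Batches are assigned by a seeded permutation (round robin).
    """
    cfg = config
    rng = _rng(seed, 4)
    replicated = set(strains[: cfg.n_replicated_strains])
    rows: list[tuple[str, str, int]] = []  # sample, strain, replicate
    for s in strains:
        k = cfg.replicates_per_strain if s in replicated else 1
        for r in range(k):
            rows.append((f"{s}_r{r}", s, r))
    design = pd.DataFrame(rows, columns=["sample", "strain", "replicate"])
    design["batch"] = [
        f"batch{i % cfg.n_batches}" for i in rng.permutation(len(design))
    ]
    return design[["sample", "strain", "batch", "replicate"]]


def expand_to_samples(
    strain_traits: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
    design: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand strain-level traits to replicated samples with batch shifts.

    sample value = strain value + batch shift + replicate noise, where the
    batch shift is a per-trait Gaussian offset shared by all samples of a
    batch.  Returns ``(samples, design)``.
    """
    cfg = config
    if design is None:
        design = make_sample_design(list(strain_traits.index), cfg, seed)
    rng = _rng(seed, 5)
    batch_shift = {
        b: rng.normal(0.0, cfg.sigma_batch, size=strain_traits.shape[1])
        for b in sorted(design["batch"].unique())
    }
    values = strain_traits.loc[design["strain"]].to_numpy(copy=True)
    for i, b in enumerate(design["batch"]):
        values[i] += batch_shift[b]
    values += rng.normal(0.0, cfg.sigma_replicate, size=values.shape)
    samples = pd.DataFrame(values, index=design["sample"].tolist(),
                           columns=strain_traits.columns)
    return samples, design


def inject_missingness(matrix: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set each cell to NaN independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    if rate == 0.0:
        return matrix.copy()
    rng = _rng(seed, 5)
    mask = rng.random(matrix.shape) < rate
    out = matrix.copy()
    out.values[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# physiology + one-call convenience
# ---------------------------------------------------------------------------

def simulate_physiology(
    geno: GenotypeData,
    layers: dict[str, pd.DataFrame],
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Physiological traits mediated by molecular traits.

    Each configured mediation triple produces one physiological trait
    y = b * mediator + c' * x + noise where the mediator itself carries the
    genotype effect a * x (enforced by adding any shortfall directly).
    Remaining traits up to ``n_physio`` are pure noise.
    """
    cfg = config
    rng = _rng(seed, 6)
    strains = geno.strains
    n = len(strains)
    cols: dict[str, np.ndarray] = {}
    med_rows = []
    for k, spec in enumerate(cfg.mediations):
        if spec.marker not in geno.calls.columns:
            raise ValueError(f"unknown mediation locus {spec.marker!r}")
        x = geno.calls[spec.marker].to_numpy()
        layer = layers[spec.mediator_layer]
        if spec.mediator_trait is None:
            mediator = f"med{k}"
            m = spec.a * x + rng.normal(0.0, 0.3, size=n)
            layer = layer.copy()
            layer[mediator] = m
            layers[spec.mediator_layer] = layer
        else:
            mediator = spec.mediator_trait
            m = layer[mediator].to_numpy()
        name = f"physio{k:02d}"
        cols[name] = spec.b * m + spec.c_prime * x + rng.normal(0.0, cfg.sigma_physio, size=n)
        med_rows.append((name, spec.marker, mediator, spec.a, spec.b, spec.c_prime))
    for k in range(len(cfg.mediations), cfg.n_physio):
        cols[f"physio{k:02d}"] = rng.normal(0.0, cfg.sigma_physio, size=n)
    physio = pd.DataFrame(cols, index=strains)
    med_df = pd.DataFrame(
        med_rows, columns=["physio_trait", "marker", "mediator", "a", "b", "c_prime"])
    return physio, med_df


def simulate_panel(config: SimulationConfig | None = None, seed: int | None = None):
    """Run the full generator: genotypes, layers, samples, physiology.

    Returns a dict with keys ``geno``, ``layers`` (strain level),
    ``samples`` (per-layer sample matrices), ``design``, ``annotations``,
    ``physio`` and ``truth``.
    """
    cfg = config or SimulationConfig()
    if seed is None:
        seed = cfg.seed
    markers = make_marker_map(cfg.chrom_lengths, cfg.marker_spacing_bp)
    geno = simulate_genotypes(markers, cfg.n_strains, seed, cfg.cm_per_kb)
    layers, annotations, truth = simulate_trait_layers(geno, cfg, seed)
    physio, med_df = simulate_physiology(geno, layers, cfg, seed)
    truth = dataclasses.replace(truth, mediation=med_df)
    design = make_sample_design(geno.strains, cfg, seed)
    samples = {}
    for li, (layer, df) in enumerate(layers.items()):
        sm, _ = expand_to_samples(df, cfg, seed * 8191 + li, design=design)
        samples[layer] = sm
    return {
        "geno": geno,
        "layers": layers,
        "samples": samples,
        "design": design,
        "annotations": annotations,
        "physio": physio,
        "truth": truth,
    }
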