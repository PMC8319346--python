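"""Synthetic data with the statistical structure the pipeline assumes.

Everything downstream — fitness estimation, hit calling, locus
delineation, O-specific-antigen (OSA) comparison, phenotype concordance,
proteomics summaries — can be exercised on data from this module alone.

The barcoded-library model: each gene carries a Poisson-distributed
number of independently barcoded transposon insertions at uniform
positions; strains have log-normal latent abundances; sequencing is a
single multinomial draw at fixed depth, so read totals are conserved
exactly. Selection multiplies a strain's latent abundance by
``2**phi_g``, where ``phi_g`` is the true log2 fitness effect of
disrupting gene g: large positive for tailocin-receptor biosynthesis
genes (disruption confers resistance, so mutants sweep), moderately
negative for self-intoxication "shield" genes. The diluted-tailocin
condition attenuates every phi; the buffer control zeroes them.

The strain-panel model: clades share an OSA orthogroup repertoire drawn
from a common pool; each simulated tailocin targets one receptor
orthogroup, and a strain is sensitive exactly when its OSA cluster
carries that receptor. An optional discordant clade mimics panels where
identical OSA content nevertheless splits in phenotype.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .loci import AnnotatedGenome, Gene

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_library",
    "simulate_selection",
    "generate_assay",
    "PanelConfig",
    "generate_strain_panel",
    "generate_empai_table",
]

CONDITIONS = ("Ctrl", "Max", "Dil")


@dataclass
class SimulationConfig:
    """Study conditions for one pooled fitness assay.

    Defaults follow the assays being emulated: ~500-gene genomes read to
    5x10^5 barcodes per sample, receptor disruptions with log2 effects
    spanning 8-16 (sweeps "up to +16"), shield disruptions in [-4, -2],
    and a tenfold-diluted treatment attenuating selection.
    """

    n_genes: int = 500
    mean_strains_per_gene: float = 2.0
    central_fraction: float = 0.8
    depth_time0: int = 500_000
    depth_after: int = 500_000
    receptor_genes: tuple[str, ...] = ()
    shield_genes: tuple[str, ...] = ()
    phi_receptor_range: tuple[float, float] = (8.0, 16.0)
    phi_shield_range: tuple[float, float] = (-4.0, -2.0)
    abundance_sd: float = 1.0
    dil_attenuation: float = 0.6
    dirichlet_alpha: float | None = None  # optional overdispersion, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.depth_time0 <= 0 or self.depth_after <= 0:
            raise ConfigurationError("sequencing depths must be positive")
        if not 0 < self.central_fraction <= 1:
            raise ConfigurationError("central_fraction must be in (0, 1]")
        if set(self.receptor_genes) & set(self.shield_genes):
            raise ConfigurationError("receptor_genes and shield_genes must be disjoint")
        for lo, hi in (self.phi_receptor_range, self.phi_shield_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ConfigurationError("phi ranges must be finite intervals")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class TruthTable:
    """Ground truth behind one simulated assay."""

    phi: dict[str, float]  # gene -> true log2 effect under Max treatment
    strains: pd.DataFrame  # barcode, locus_tag, gene_fraction, abundance

    def phi_for(self, condition: str, dil_attenuation: float) -> dict[str, float]:
        if condition == "Ctrl":
            return {g: 0.0 for g in self.phi}
        if condition == "Max":
            return dict(self.phi)
        if condition == "Dil":
            return {g: v * dil_attenuation for g, v in self.phi.items()}
        raise ConfigurationError(f"unknown condition {condition!r}")


def _spread(values: tuple[float, float], n: int) -> np.ndarray:
    """Evenly spaced effects across a range, endpoints included.

    With a single gene the strong endpoint is used, so the configured
    maximum effect is always represented.
    """
    lo, hi = values
    if n == 1:
        return np.array([hi if abs(hi) >= abs(lo) else lo])
    return np.linspace(lo, hi, n)


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = ["".join(alphabet[rng.integers(0, 4, size=length)]) for _ in range(n - len(out))]
        for bc in draw:
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def generate_library(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, TruthTable]:
    """Build a barcoded mutant pool and its Time0 count vector.

    Returns ``(pool, time0, truth)``: the pool table (barcode, scaffold,
    strand, pos, locus_tag, gene_fraction), Time0 counts (a multinomial
    draw summing exactly to ``depth_time0``), and the truth table with
    per-gene effects and latent strain abundances.
    """
    rng = np.random.default_rng([config.seed, _label_key("library")])
    genes = config.gene_ids()
    for g in list(config.receptor_genes) + list(config.shield_genes):
        if g not in set(genes):
            raise ConfigurationError(f"spiked gene {g!r} is not in the simulated genome")

    phi = {g: 0.0 for g in genes}
    for gid, val in zip(config.receptor_genes, _spread(config.phi_receptor_range, len(config.receptor_genes))):
        phi[gid] = float(val)
    for gid, val in zip(config.shield_genes, _spread(config.phi_shield_range, len(config.shield_genes))):
        phi[gid] = float(val)

    n_strains_per_gene = 1 + rng.poisson(max(config.mean_strains_per_gene - 1.0, 0.0), size=config.n_genes)
    locus = np.repeat(genes, n_strains_per_gene)
    n_total = int(n_strains_per_gene.sum())

    # insertion positions: central_fraction of mass inside [0.1, 0.9]
    central = rng.random(n_total) < config.central_fraction
    frac = np.where(
        central,
        rng.uniform(0.1, 0.9, size=n_total),
        np.where(rng.random(n_total) < 0.5, rng.uniform(0.0, 0.1, n_total), rng.uniform(0.9, 1.0, n_total)),
    )
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sd, size=n_total)
    barcodes = _random_barcodes(rng, n_total)

    gene_index = {g: i for i, g in enumerate(genes)}
    pool = pd.DataFrame(
        {
            "barcode": barcodes,
            "scaffold": "chr1",
            "strand": np.where(rng.random(n_total) < 0.5, "+", "-"),
            "pos": [gene_index[g] * 1000 + 1 + int(f * 900) for g, f in zip(locus, frac)],
            "locus_tag": locus,
            "gene_fraction": frac,
        }
    )

    p = abundance / abundance.sum()
    time0 = pd.Series(
        rng.multinomial(config.depth_time0, p), index=pd.Index(barcodes, name="barcode"), name="Time0"
    )
    truth = TruthTable(
        phi=phi,
        strains=pd.DataFrame(
            {
                "barcode": barcodes,
                "locus_tag": locus,
                "gene_fraction": frac,
                "abundance": abundance,
            }
        ),
    )
    return pool, time0, truth


def _label_key(label: str) -> int:
    """Stable 32-bit stream key for a sample label."""
    return zlib.crc32(label.encode())


def simulate_selection(
    time0: pd.Series,
    truth: TruthTable,
    condition: str,
    config: SimulationConfig,
    sample_name: str | None = None,
) -> pd.Series:
    """Draw a post-selection count vector for one treated sample.

    Selection acts on the latent abundances, not the observed Time0
    counts: ``a'_s = a_s * 2**phi_g(condition)``, renormalized and read
    multinomially to ``depth_after`` total reads. ``sample_name`` keys an
    independent random stream (replicates of the same condition pass
    different names).
    """
    phi = truth.phi_for(condition, config.dil_attenuation)
    label = sample_name or condition
    rng = np.random.default_rng([config.seed, _label_key(label)])

    strains = truth.strains
    effect = strains["locus_tag"].map(phi).to_numpy(float)
    a_post = strains["abundance"].to_numpy(float) * np.exp2(effect)
    p = a_post / a_post.sum()
    if config.dirichlet_alpha is not None:
        p = rng.dirichlet(p * config.dirichlet_alpha)
    counts = rng.multinomial(config.depth_after, p)
    return pd.Series(counts, index=pd.Index(strains["barcode"], name="barcode"), name=label)


def generate_assay(
    config: SimulationConfig,
    n_replicates: int = 2,
    conditions: tuple[str, ...] = CONDITIONS,
    tailocin_source: str = "Pse04",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Full experiment: pool, count matrix, sample sheet, truth.

    Assays run in duplicate by default, each replicate with its own
    Time0 sample; treated samples are paired to the Time0 of their
    replicate via the ``time0_sample`` column.
    """
    pool, _, truth = generate_library(config)
    columns: dict[str, pd.Series] = {}
    meta_rows = []
    rng_keys = np.random.default_rng([config.seed, _label_key("time0-replicates")])
    p = truth.strains["abundance"].to_numpy(float)
    p = p / p.sum()
    for rep in range(1, n_replicates + 1):
        t0_name = f"Time0_r{rep}"
        columns[t0_name] = pd.Series(
            rng_keys.multinomial(config.depth_time0, p),
            index=pd.Index(truth.strains["barcode"], name="barcode"),
            name=t0_name,
        )
        meta_rows.append(
            {"sample": t0_name, "condition": "Time0", "replicate": rep, "is_time0": True,
             "tailocin_source": "", "time0_sample": ""}
        )
        for cond in conditions:
            name = f"{cond}_r{rep}"
            columns[name] = simulate_selection(columns[t0_name], truth, cond, config, sample_name=name)
            meta_rows.append(
                {"sample": name, "condition": cond, "replicate": rep, "is_time0": False,
                 "tailocin_source": tailocin_source, "time0_sample": t0_name}
            )
    counts = pd.DataFrame(columns)
    samples = pd.DataFrame(meta_rows)
    return pool, counts, samples, truth


# ---------------------------------------------------------------------------
# strain panel (comparative genomics side)
# ---------------------------------------------------------------------------

_PHAGE_PRODUCTS = [
    "phage tail fiber protein",
    "tail sheath protein",
    "tail tube protein",
    "baseplate assembly protein",
    "tail spike protein",
    "holin",
    "lysis protein",
    "phage tail protein",
    "phage baseplate wedge",
    "tail fibre assembly chaperone",
]

PAO1_CORE_RANGE = [f"PA{i}" for i in range(4997, 5013)]  # LPS core oligosaccharide
PAO1_CPA_RANGE = [f"PA{i}" for i in range(5447, 5460)]  # common polysaccharide antigen


@dataclass
class PanelConfig:
    """Study conditions for the comparative strain panel.

    Defaults mirror the phenotyping panel being emulated: 130 strains in
    12 OSA clades, four tailocin samples, phenotype fully determined by
    the presence of each tailocin's receptor orthogroup in the OSA
    cluster.
    """

    n_strains: int = 130
    n_clades: int = 12
    osa_pool_size: int = 80
    osa_cluster_size: int = 12
    within_clade_divergence: float = 0.0
    n_tailocins: int = 4
    sm_like_clade: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades > self.n_strains:
            raise ConfigurationError("n_clades must not exceed n_strains")
        if self.osa_cluster_size > self.osa_pool_size:
            raise ConfigurationError("orthogroup pool smaller than requested cluster size")
        if not 0 <= self.within_clade_divergence <= 1:
            raise ConfigurationError("within_clade_divergence must be in [0, 1]")


def _make_genome(
    strain: str,
    osa_orthogroups: list[str],
    rng: np.random.Generator,
    tailocin_og_prefix: str = "OGtail",
) -> AnnotatedGenome:
    """One-contig genome with anchored tailocin, OSA, core and CPA loci."""
    genes: list[Gene] = []
    cursor = 1
    counter = 0

    def add(product: str, name: str | None = None, orthogroup: str | None = None) -> None:
        nonlocal cursor, counter
        counter += 1
        start = cursor
        end = start + 899
        cursor = end + 101
        genes.append(
            Gene(
                locus_tag=f"{strain}_{counter:04d}",
                contig="contig1",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=product,
                orthogroup=orthogroup,
                name=name,
            )
        )

    for i in range(3):
        add("hypothetical protein")
    add("DNA mismatch repair protein MutS", name="mutS", orthogroup="OGmutS")
    # tailocin locus: 12 genes, phage-structural products, no capsid/terminase/integrase
    for i in range(12):
        product = _PHAGE_PRODUCTS[i % len(_PHAGE_PRODUCTS)] if i % 2 == 0 or i < 6 else "hypothetical protein"
        add(product, orthogroup=f"{tailocin_og_prefix}{i:02d}")
    add("competence/damage-inducible protein CinA", name="cinA", orthogroup="OGcinA")
    for i in range(2):
        add("hypothetical protein")
    add("integration host factor subunit beta", name="ihfB", orthogroup="OGihfB")
    for og in osa_orthogroups:
        add("O-antigen biosynthesis protein", orthogroup=og)
    add("polysaccharide biosynthesis protein WbpM", name="wbpM", orthogroup="OGwbpM")
    for i in range(2):
        add("hypothetical protein")
    for tag in PAO1_CORE_RANGE:
        add("LPS core oligosaccharide biosynthesis protein", orthogroup=f"OGcore_{tag}")
    for tag in PAO1_CPA_RANGE:
        add("common polysaccharide antigen biosynthesis protein", orthogroup=f"OGcpa_{tag}")
    return AnnotatedGenome(strain=strain, contigs={"contig1": genes})


def pao1_ortholog_map() -> dict[str, str]:
    """PAO1 locus tag -> orthogroup id, for the panel's core/CPA clusters."""
    out = {tag: f"OGcore_{tag}" for tag in PAO1_CORE_RANGE}
    out.update({tag: f"OGcpa_{tag}" for tag in PAO1_CPA_RANGE})
    return out


def generate_strain_panel(
    config: PanelConfig,
) -> tuple[list[AnnotatedGenome], pd.DataFrame, dict]:
    """Simulate a genome panel plus its true sensitivity matrix.

    Returns ``(genomes, sensitivity, truth)``. ``sensitivity`` is a
    strain x tailocin DataFrame of ``"sensitive"``/``"resistant"``;
    ``truth`` records clade membership, per-tailocin receptor
    orthogroups, producer strains (each chosen resistant to its own
    sample, so no self-kill), each strain's OSA orthogroup set, and —
    when ``sm_like_clade`` is on — which clade was made discordant and
    which of its members were flipped.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, _label_key("panel")])
    pool = [f"OG{i:04d}" for i in range(1, cfg.osa_pool_size + 1)]

    clade_sets: list[list[str]] = []
    for c in range(cfg.n_clades):
        chosen = rng.choice(cfg.osa_pool_size, size=cfg.osa_cluster_size, replace=False)
        clade_sets.append(sorted(pool[i] for i in chosen))

    # receptor orthogroup per tailocin: drawn from clade repertoires so that
    # some clades are sensitive and some are not
    receptors = {}
    for t in range(cfg.n_tailocins):
        clade = int(rng.integers(0, cfg.n_clades))
        og = clade_sets[clade][int(rng.integers(0, cfg.osa_cluster_size))]
        receptors[f"T{t + 1:02d}"] = og

    base = cfg.n_strains // cfg.n_clades
    sizes = [base + (1 if i < cfg.n_strains % cfg.n_clades else 0) for i in range(cfg.n_clades)]
    genomes: list[AnnotatedGenome] = []
    clade_of: dict[str, int] = {}
    osa_sets: dict[str, list[str]] = {}
    idx = 0
    for c, size in enumerate(sizes):
        for _ in range(size):
            idx += 1
            strain = f"S{idx:03d}"
            ogs = list(clade_sets[c])
            if cfg.within_clade_divergence > 0:
                keep = rng.random(len(ogs)) >= cfg.within_clade_divergence
                swapped = [og for og, k in zip(ogs, keep) if k]
                n_new = len(ogs) - len(swapped)
                extra = [og for og in pool if og not in clade_sets[c]]
                if n_new:
                    swapped += list(rng.choice(extra, size=min(n_new, len(extra)), replace=False))
                ogs = sorted(swapped)
            clade_of[strain] = c
            osa_sets[strain] = ogs
            genomes.append(_make_genome(strain, ogs, rng))

    sens = pd.DataFrame(
        {
            t: ["sensitive" if receptors[t] in osa_sets[s] else "resistant" for s in clade_of]
            for t in receptors
        },
        index=pd.Index(list(clade_of), name="strain"),
    )

    truth: dict = {
        "clade_of": clade_of,
        "receptors": receptors,
        "osa_sets": {s: list(v) for s, v in osa_sets.items()},
        "sm_clade": None,
        "sm_flipped": [],
    }

    if cfg.sm_like_clade:
        # a clade with identical OSA content but split phenotype for one tailocin
        sm = int(rng.integers(0, cfg.n_clades))
        members = [s for s, c in clade_of.items() if c == sm]
        col = list(receptors)[0]
        flip = members[: len(members) // 2 + len(members) % 2]
        for s in flip:
            sens.loc[s, col] = "resistant" if sens.loc[s, col] == "sensitive" else "sensitive"
        truth["sm_clade"] = sm
        truth["sm_flipped"] = flip
        truth["sm_column"] = col

    # producers: for each tailocin pick a strain resistant to it (self-resistance)
    producers = {}
    for t in receptors:
        resistant = [s for s in sens.index if sens.loc[s, t] == "resistant"]
        producers[t] = resistant[0] if resistant else None
    truth["producers"] = producers
    return genomes, sens, truth


def generate_empai_table(
    n_proteins: int,
    tailocin_fraction_target: float,
    seed: int = 0,
    sample: str = "sample1",
) -> pd.DataFrame:
    """Shotgun-proteomics emPAI table with a known tailocin molar fraction.

    Log-normal emPAI values; roughly a tenth of the proteins are flagged
    as tailocin-cluster products and their values rescaled so the
    tailocin molar fraction hits the target.
    """
    if not 0 < tailocin_fraction_target < 100:
        raise ConfigurationError("tailocin_fraction_target must be in (0, 100)")
    if n_proteins < 2:
        raise ConfigurationError("need at least 2 proteins for a proper mixture")
    rng = np.random.default_rng([seed, _label_key("empai")])
    values = rng.lognormal(mean=0.0, sigma=1.0, size=n_proteins)
    k = max(1, n_proteins // 10)
    is_tail = np.zeros(n_proteins, dtype=bool)
    is_tail[rng.choice(n_proteins, size=k, replace=False)] = True

    target = tailocin_fraction_target / 100.0
    s_t, s_o = values[is_tail].sum(), values[~is_tail].sum()
    values[is_tail] *= (target / (1 - target)) * (s_o / s_t)
    return pd.DataFrame(
        {
            "protein": [f"P{i + 1:04d}" for i in range(n_proteins)],
            "sample": sample,
            "empai": values,
            "is_tailocin": is_tail,
        }
    )
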