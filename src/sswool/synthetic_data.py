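"""Synthetic data with known ground truth for every downstream stage.

The generator emulates the structure of a Merino-style breeding study:
a multi-generation pedigree with only a fraction of the phenotyped females
genotyped, six traits with heritabilities between 0.05 and 0.36 under a
flock/birth-year/season fixed-effect structure, an additive architecture
mixing explicit QTL with an infinitesimal polygenic background, and a
multi-tissue expression atlas (87 tissues in 13 organ systems) with planted
tissue-specific genes.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SimConfig.seed``; independent substreams per operation keep the stages
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    GenotypeMatrix,
    MarkerMap,
    PedigreeTable,
    PhenotypeTable,
    SampleMetadata,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_pedigree",
    "simulate_marker_map",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_expression_atlas",
    "default_atlas_metadata",
    "sample_genotyped_ids",
    "ORGAN_SYSTEMS",
]

# the 13 organ systems of the expression atlas
ORGAN_SYSTEMS = [
    "CNS",
    "Cardio",
    "Skin",
    "Muscle",
    "Liver",
    "Lung",
    "Kidney",
    "GI",
    "Endocrine",
    "Immune",
    "Male_R",
    "Fem_R",
    "Embryonic",
]

# default trait panel: target h2 and phenotypic variance per trait
DEFAULT_H2 = {
    "MFD": 0.36,
    "CVFD": 0.05,
    "CN": 0.07,
    "MSL": 0.27,
    "GFW": 0.28,
    "LW": 0.33,
}
DEFAULT_PHENOTYPIC_VARIANCE = {
    "MFD": 2.91,
    "CVFD": 6.76,
    "CN": 5.28,
    "MSL": 0.80,
    "GFW": 0.30,
    "LW": 18.30,
}
DEFAULT_TRAIT_MEANS = {
    "MFD": 18.24,
    "CVFD": 21.98,
    "CN": 12.71,
    "MSL": 10.26,
    "GFW": 3.95,
    "LW": 36.56,
}
# default genetic correlation targets (unlisted pairs default to 0)
DEFAULT_RG = {
    ("GFW", "LW"): 0.77,
    ("CN", "LW"): -0.44,
    ("MFD", "MSL"): 0.29,
    ("MSL", "LW"): 0.29,
    ("MSL", "GFW"): 0.27,
    ("MFD", "CVFD"): -0.21,
}


class ConfigError(ValueError):
    """Impossible simulation configuration."""


@dataclass
class SimConfig:
    """Simulation knobs (defaults emulate a commercial fine-wool breeding
    design at desk scale: ~1000 animals, 1000 SNPs on 5 chromosomes)."""

    n_founders: int = 200
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_chromosomes: int = 5
    markers_per_chromosome: int = 200
    chromosome_length_bp: int = 100_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 20
    qtl_variance_fraction: float = 0.3
    target_h2: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_H2))
    phenotypic_variance: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPIC_VARIANCE)
    )
    trait_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    genetic_correlation_targets: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RG)
    )
    fixed_effect_levels: tuple[int, int, int] = (50, 8, 2)  # flock, year, season
    genotyped_fraction: float = 0.17  # most phenotyped animals lack genotypes
    phenotyped_sex: str = "F"  # yearling-female recording scheme; "both" lifts it
    qtl_effect_distribution: str = "normal"  # or "equal": same |effect|, random sign
    qtl_marker_indices: tuple[int, ...] | None = None  # explicit placement; overrides n_qtl
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("founder_maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.qtl_variance_fraction <= 1):
            raise ConfigError("qtl_variance_fraction must lie in [0, 1]")
        if self.n_qtl > self.n_chromosomes * self.markers_per_chromosome:
            raise ConfigError("n_qtl exceeds total marker count")
        if not (0 < self.genotyped_fraction <= 1):
            raise ConfigError("genotyped_fraction must lie in (0, 1]")
        for t, h2 in self.target_h2.items():
            if not (0 <= h2 < 1):
                raise ConfigError(f"target h2 for {t} must lie in [0, 1)")

    @property
    def traits(self) -> list[str]:
        return list(self.target_h2)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthRecord:
    """Ground truth carried alongside the synthetic observations."""

    true_breeding_values: pd.DataFrame | None = None  # animals x traits
    qtl: pd.DataFrame | None = None  # chromosome, position_bp, marker_index, effect_<trait>
    sigma2_a: dict[str, float] | None = None
    sigma2_e: dict[str, float] | None = None
    genetic_covariance: pd.DataFrame | None = None
    planted_tissue_specific_genes: dict[str, set[str]] | None = None


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> tuple[PedigreeTable, pd.Series]:
    """Non-overlapping-generation random-mating pedigree.

    Returns the topologically sorted pedigree plus a per-animal sex series
    ("M"/"F", indexed by animal id); sex drives the phenotyped-female design
    and is not part of the pedigree file format.
    """
    if config.n_founders < 2:
        raise ConfigError("need at least 2 founders (one of each sex)")
    rng = config.rng(1)
    animals: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    sexes: list[str] = []

    founders = [f"G0_{i:05d}" for i in range(config.n_founders)]
    founder_sex = ["M" if i % 2 == 0 else "F" for i in range(config.n_founders)]
    animals.extend(founders)
    sires.extend([None] * config.n_founders)
    dams.extend([None] * config.n_founders)
    sexes.extend(founder_sex)

    prev = list(zip(founders, founder_sex))
    for g in range(1, config.n_generations + 1):
        males = [a for a, s in prev if s == "M"]
        females = [a for a, s in prev if s == "F"]
        n_mat = min(len(males), len(females))
        if n_mat == 0:
            raise ConfigError(f"generation {g}: no possible matings (need both sexes)")
        males = list(rng.permutation(males)[:n_mat])
        females = list(rng.permutation(females)[:n_mat])
        cur: list[tuple[str, str]] = []
        k = 0
        for s, d in zip(males, females):
            for _ in range(config.offspring_per_mating):
                a = f"G{g}_{k:05d}"
                sx = "M" if rng.random() < 0.5 else "F"
                animals.append(a)
                sires.append(s)
                dams.append(d)
                sexes.append(sx)
                cur.append((a, sx))
                k += 1
        prev = cur
    ped = PedigreeTable(animals, sires, dams)
    return ped, pd.Series(sexes, index=animals, name="sex")


def simulate_marker_map(config: SimConfig) -> MarkerMap:
    """Uniformly placed markers with strictly increasing positions."""
    rng = config.rng(2)
    chroms, snps, pos = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        m = config.markers_per_chromosome
        # strictly increasing ~uniform positions without materializing the
        # whole coordinate range
        p = np.sort(rng.integers(1, config.chromosome_length_bp - m + 1, size=m)) + np.arange(m)
        pos.append(p)
        chroms.extend([str(c)] * config.markers_per_chromosome)
        snps.extend([f"snp{c}_{j:05d}" for j in range(config.markers_per_chromosome)])
    return MarkerMap(np.array(snps, dtype=object), np.array(chroms, dtype=object), np.concatenate(pos))


# ---------------------------------------------------------------------------
# genotypes: gene dropping with Haldane recombination at 1 cM/Mb
# ---------------------------------------------------------------------------

MORGAN_PER_BP = 1e-8  # 1 cM/Mb


def _recombination_probs(positions: np.ndarray) -> np.ndarray:
    """Haldane map: r between adjacent markers from the bp distance."""
    d = np.diff(positions).astype(np.float64) * MORGAN_PER_BP
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _gamete(hap_pair: np.ndarray, rec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Recombine one parent's two haplotypes into a transmitted gamete."""
    m = hap_pair.shape[1]
    switches = rng.random(m - 1) < rec if m > 1 else np.empty(0, dtype=bool)
    source = np.empty(m, dtype=np.int8)
    source[0] = rng.integers(2)
    if m > 1:
        source[1:] = (source[0] + np.cumsum(switches)) % 2
    return hap_pair[source, np.arange(m)]


def simulate_genotypes(
    pedigree: PedigreeTable, marker_map: MarkerMap, config: SimConfig
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop genes down the pedigree; returns genotypes for *all* animals plus
    the founder allele frequencies used (per marker).

    Founders are drawn in Hardy-Weinberg proportions; an unknown parent's
    gamete is drawn from the founder frequencies.
    """
    rng = config.rng(3)
    n = len(pedigree)
    m = len(marker_map)
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, size=m)

    # per-chromosome recombination probabilities, concatenated with a forced
    # switch-prob 0.5 at chromosome boundaries (independent assortment)
    rec = np.empty(max(m - 1, 0))
    chrom = marker_map.chromosome
    if m > 1:
        start = 0
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            r = _recombination_probs(marker_map.position_bp[idx])
            rec[idx[0] : idx[0] + len(r)] = r
            if idx[0] > 0:
                rec[idx[0] - 1] = 0.5
            start = idx[-1]

    haps = np.empty((n, 2, m), dtype=np.int8)
    founder = pedigree.is_founder()
    for i in range(n):
        si, di = pedigree.sire_idx[i], pedigree.dam_idx[i]
        for slot, pi in ((0, si), (1, di)):
            if pi < 0:
                haps[i, slot] = rng.random(m) < p
            else:
                haps[i, slot] = _gamete(haps[pi], rec, rng)
    dosage = haps.sum(axis=1).astype(np.float64)
    return GenotypeMatrix(dosage, list(pedigree.animals)), p


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _correlation_matrix(traits: list[str], targets: Mapping[tuple[str, str], float]) -> np.ndarray:
    """Assemble the genetic correlation matrix from pairwise targets and
    project to the nearest PSD correlation matrix (eigenvalue clipping)."""
    t = len(traits)
    pos = {name: i for i, name in enumerate(traits)}
    r = np.eye(t)
    for (a, b), v in targets.items():
        if a in pos and b in pos:
            r[pos[a], pos[b]] = r[pos[b], pos[a]] = float(v)
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        r = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def simulate_phenotypes(
    pedigree: PedigreeTable,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    sexes: pd.Series | None = None,
) -> tuple[PhenotypeTable, TruthRecord]:
    """QTL + infinitesimal breeding values bred down the pedigree, plus
    fixed effects and residual noise.

    Breeding value = sum of centered QTL dosages times effects (scaled to
    ``qtl_variance_fraction`` of sigma2_a among founders) + a polygenic term
    (founders ~ N(0, (1-f) sigma2_a); offspring = parent average + Mendelian
    sampling, variance halved per known parent).  Fixed-effect level values
    are drawn once per level from N(0, (0.5 sd_p)^2).
    """
    traits = config.traits
    n = len(pedigree)
    rng = config.rng(4)
    sig_p = np.array([config.phenotypic_variance[t] for t in traits])
    h2 = np.array([config.target_h2[t] for t in traits])
    sig_a = h2 * sig_p
    sig_e = sig_p - sig_a
    r_g = _correlation_matrix(traits, config.genetic_correlation_targets)
    f_qtl = config.qtl_variance_fraction

    # --- QTL component -----------------------------------------------------
    m = genotypes.n_markers
    if config.qtl_marker_indices is not None:
        qtl_idx = np.sort(np.asarray(config.qtl_marker_indices, dtype=int))
        n_qtl = len(qtl_idx)
    else:
        n_qtl = config.n_qtl
        qtl_idx = np.sort(rng.choice(m, size=n_qtl, replace=False)) if n_qtl else np.empty(0, int)
    chol = np.linalg.cholesky(r_g)
    raw_eff = rng.standard_normal((n_qtl, len(traits))) @ chol.T
    if config.qtl_effect_distribution == "equal" and n_qtl:
        # equal-magnitude planted effects (random sign): every QTL carries a
        # comparable share of the planted variance
        raw_eff = np.sign(raw_eff) * 1.0
    elif config.qtl_effect_distribution != "normal":
        raise ConfigError(f"unknown qtl_effect_distribution {config.qtl_effect_distribution!r}")
    z_qtl = genotypes.dosage[:, qtl_idx]
    z_qtl = z_qtl - z_qtl.mean(axis=0)
    g_qtl = z_qtl @ raw_eff  # n x traits, unscaled
    founders = pedigree.is_founder()
    scale = np.ones(len(traits))
    if n_qtl:
        v_founder = g_qtl[founders].var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.sqrt(np.where(v_founder > 0, f_qtl * sig_a / v_founder, 0.0))
    g_qtl = g_qtl * scale
    effects = raw_eff * scale  # per-dosage effects on trait scale

    # --- polygenic component ----------------------------------------------
    sig_poly = (1.0 - f_qtl) * sig_a
    cov_poly = np.sqrt(np.outer(sig_poly, sig_poly)) * r_g
    if np.trace(cov_poly) > 0:
        jitter = 1e-12 * np.trace(cov_poly) / len(traits)
        l_poly = np.linalg.cholesky(cov_poly + jitter * np.eye(len(traits)))
    else:
        l_poly = np.zeros_like(cov_poly)
    std = rng.standard_normal((n, len(traits))) @ l_poly.T
    poly = np.zeros((n, len(traits)))
    s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        si, di = s_idx[i], d_idx[i]
        pa = np.zeros(len(traits))
        known = 0
        if si >= 0:
            pa += 0.5 * poly[si]
            known += 1
        if di >= 0:
            pa += 0.5 * poly[di]
            known += 1
        ms_var = 1.0 - 0.25 * known  # 1, 0.75 or 0.5 of the base variance
        poly[i] = pa + np.sqrt(ms_var) * std[i]

    tbv = g_qtl + poly

    # --- fixed effects, residuals, assembly --------------------------------
    n_flock, n_year, n_season = config.fixed_effect_levels
    sd_p = np.sqrt(sig_p)
    flock_eff = rng.normal(0.0, 0.5 * sd_p, size=(n_flock, len(traits)))
    year_eff = rng.normal(0.0, 0.5 * sd_p, size=(n_year, len(traits)))
    season_eff = rng.normal(0.0, 0.5 * sd_p, size=(n_season, len(traits)))
    flock = rng.integers(n_flock, size=n)
    year = rng.integers(n_year, size=n)
    season = rng.integers(n_season, size=n)
    resid = rng.standard_normal((n, len(traits))) * np.sqrt(sig_e)
    mu = np.array([config.trait_means[t] for t in traits])
    y = mu + flock_eff[flock] + year_eff[year] + season_eff[season] + tbv + resid

    if sexes is not None and config.phenotyped_sex in ("M", "F"):
        phenotyped = (sexes.reindex(pedigree.animals).to_numpy() == config.phenotyped_sex) & ~founders
    else:
        phenotyped = ~founders
    if not phenotyped.any():
        phenotyped = np.ones(n, dtype=bool)

    data = pd.DataFrame(
        {
            "animal": np.array(pedigree.animals, dtype=object)[phenotyped],
            "flock": [f"flock{v:02d}" for v in flock[phenotyped]],
            "birth_year": [f"y{2011 + v}" for v in year[phenotyped]],
            "season": ["spring" if v == 0 else "winter" for v in season[phenotyped]],
        }
    )
    for j, t in enumerate(traits):
        data[t] = y[phenotyped, j]

    qtl_table = pd.DataFrame(
        {
            "marker_index": qtl_idx,
            **{f"effect_{t}": effects[:, j] for j, t in enumerate(traits)},
        }
    )
    truth = TruthRecord(
        true_breeding_values=pd.DataFrame(tbv, index=pedigree.animals, columns=traits),
        qtl=qtl_table,
        sigma2_a={t: float(v) for t, v in zip(traits, sig_a)},
        sigma2_e={t: float(v) for t, v in zip(traits, sig_e)},
        genetic_covariance=pd.DataFrame(
            np.sqrt(np.outer(sig_a, sig_a)) * r_g, index=traits, columns=traits
        ),
    )
    return PhenotypeTable(data, traits), truth


def sample_genotyped_ids(phenotypes: PhenotypeTable, config: SimConfig) -> list[str]:
    """Random subset of phenotyped animals observed as genotyped
    (the single-step setting: most phenotyped animals lack genotypes)."""
    rng = config.rng(5)
    ids = phenotypes.data["animal"].tolist()
    k = max(1, int(round(config.genotyped_fraction * len(ids))))
    return sorted(rng.choice(ids, size=k, replace=False).tolist())


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def simulate_gene_annotation(
    n_genes: int,
    config: SimConfig,
    gene_length_bp: int = 30_000,
) -> "GeneAnnotation":
    """Genes placed uniformly over the simulated chromosomes, ids matching
    the expression atlas (gene00000, ...)."""
    from .data_io import GeneAnnotation

    rng = config.rng(7)
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n_genes)
    starts = rng.integers(1, max(config.chromosome_length_bp - gene_length_bp, 2), size=n_genes)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{g:05d}" for g in range(n_genes)],
            "chromosome": chroms.astype(str),
            "start_bp": starts,
            "end_bp": starts + gene_length_bp - 1,
            "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
        }
    ).sort_values(["chromosome", "start_bp"], ignore_index=True)
    return GeneAnnotation(df)


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------


def default_atlas_metadata(
    n_tissues: int = 87,
    n_systems: int = 13,
    samples_per_tissue: int = 6,
) -> SampleMetadata:
    """An 87-tissue / 13-organ-system / ~500-sample layout with three age
    stages and both sexes, mirroring a multi-tissue atlas design."""
    systems = ORGAN_SYSTEMS[:n_systems]
    rows = []
    ages = ["embryo", "lamb", "adult"]
    for t in range(n_tissues):
        sys_name = systems[t % n_systems]
        tissue = f"{sys_name.lower()}_tissue{t // n_systems}"
        for s in range(samples_per_tissue):
            rows.append(
                {
                    "sample_id": f"s_{t:03d}_{s}",
                    "tissue": tissue,
                    "organ_system": sys_name,
                    "age_stage": ages[s % 3],
                    "sex": "M" if s % 2 == 0 else "F",
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


def simulate_expression_atlas(
    n_genes: int,
    metadata: SampleMetadata | None = None,
    spec_fraction: float = 0.1,
    fold_change: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata, TruthRecord]:
    """Log-normal baseline expression with planted tissue-specific genes.

    A ``spec_fraction`` of genes is assigned (round-robin over tissues) a
    +log2(fold_change) shift in its target tissue; per-sample Gaussian noise
    on the log2 scale; columns rescaled to TPM (sum 1e6).
    """
    if not (0 < spec_fraction < 0.5):
        raise ConfigError("spec_fraction must lie in (0, 0.5)")
    if fold_change < 1:
        raise ConfigError("fold_change must be >= 1")
    if metadata is None:
        metadata = default_atlas_metadata()
    counts = metadata.table.groupby("tissue").size()
    if (counts < 2).any():
        raise ConfigError("every tissue needs at least 2 samples")
    rng = np.random.default_rng([int(seed), 6])
    samples = metadata.table["sample_id"].tolist()
    tissues = metadata.tissues()
    tissue_of = metadata.table.set_index("sample_id")["tissue"]
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]

    base = rng.normal(4.0, 2.0, size=n_genes)
    log2 = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, len(samples)))

    n_spec = int(round(spec_fraction * n_genes))
    spec_genes = rng.choice(n_genes, size=n_spec, replace=False)
    planted: dict[str, set[str]] = {t: set() for t in tissues}
    boost = np.log2(fold_change)
    sample_tissue = tissue_of.reindex(samples).to_numpy()
    for k, g in enumerate(spec_genes):
        t = tissues[k % len(tissues)]
        planted[t].add(gene_ids[g])
        log2[g, sample_tissue == t] += boost

    expr = np.power(2.0, log2)
    expr = expr / expr.sum(axis=0, keepdims=True) * 1e6
    truth = TruthRecord(planted_tissue_specific_genes=planted)
    return ExpressionMatrix(expr, gene_ids, samples), metadata, truth
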