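import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sswool.data_io import GenotypeMatrix, MarkerMap, PedigreeTable, PhenotypeTable
from sswool.synthetic_data import (
    SimConfig,
    sample_genotyped_ids,
    simulate_genotypes,
    simulate_marker_map,
    simulate_pedigree,
    simulate_phenotypes,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def trio_pedigree() -> PedigreeTable:
    return PedigreeTable(["sire", "dam", "kid"], [None, None, "sire"], [None, None, "dam"])


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    d = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
            [0, 2, 2, 0],
            [1, 0, 1, 2],
        ],
        dtype=float,
    )
    return GenotypeMatrix(d, [f"i{k}" for k in range(5)])


def small_single_trait_sim(seed: int, h2: float = 0.30, **overrides):
    """Single-trait simulation helper shared by REML/GWAS tests."""
    kw = dict(
        n_founders=overrides.pop("n_founders", 150),
        n_generations=overrides.pop("n_generations", 2),
        target_h2={"T": h2},
        phenotypic_variance={"T": 1.0},
        trait_means={"T": 0.0},
        genetic_correlation_targets={},
        fixed_effect_levels=overrides.pop("fixed_effect_levels", (5, 3, 2)),
        phenotyped_sex="both",
        seed=seed,
    )
    kw.update(overrides)
    cfg = SimConfig(**kw)
    ped, sexes = simulate_pedigree(cfg)
    mm = simulate_marker_map(cfg)
    geno, founder_p = simulate_genotypes(ped, mm, cfg)
    phen, truth = simulate_phenotypes(ped, geno, cfg, sexes)
    return cfg, ped, mm, geno, phen, truth


@pytest.fixture(scope="session")
def medium_sim():
    """A moderately sized single-trait dataset reused across modules."""
    cfg = SimConfig(
        n_founders=200,
        n_generations=2,
        markers_per_chromosome=150,
        n_chromosomes=3,
        target_h2={"T": 0.30},
        phenotypic_variance={"T": 1.0},
        trait_means={"T": 0.0},
        genetic_correlation_targets={},
        fixed_effect_levels=(5, 3, 2),
        n_qtl=5,
        qtl_variance_fraction=0.5,
        genotyped_fraction=0.8,
        phenotyped_sex="both",
        seed=11,
    )
    ped, sexes = simulate_pedigree(cfg)
    mm = simulate_marker_map(cfg)
    geno, _ = simulate_genotypes(ped, mm, cfg)
    phen, truth = simulate_phenotypes(ped, geno, cfg, sexes)
    gids = sample_genotyped_ids(phen, cfg)
    sub = GenotypeMatrix(geno.dosage[ped.index_of(gids)].copy(), gids)
    return dict(cfg=cfg, ped=ped, mm=mm, geno_all=geno, geno=sub, phen=phen, truth=truth)
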