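"""Marker/individual quality control, allele frequencies, Hardy-Weinberg
exact testing, phenotype outlier removal, and LD statistics.

QC thresholds default to the standard SNP-array screen: SNP and individual
call rate >= 90%, MAF >= 1%, HWE exact P >= 1e-6, positions required,
autosomes only.  Removal order is: unmapped -> sex chromosomes ->
individual call rate -> SNP call rate -> MAF -> HWE, with allele
frequencies recomputed after individual removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, MarkerMap, PhenotypeTable

__all__ = [
    "AlleleFrequencies",
    "QcReport",
    "allele_frequencies",
    "hwe_exact_test",
    "qc_filter",
    "phenotype_outlier_filter",
    "ld_r2",
    "ld_decay",
]


@dataclass
class AlleleFrequencies:
    """Frequency of the counted (A1) allele per marker, non-missing calls
    only; markers with no calls at all are flagged in ``all_missing``."""

    p: np.ndarray
    all_missing: np.ndarray

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class QcReport:
    removed_markers: dict[str, int] = field(default_factory=dict)
    removed_individuals: int = 0
    thresholds: dict[str, float] = field(default_factory=dict)
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_markers": dict(self.removed_markers),
            "removed_individuals": self.removed_individuals,
            "thresholds": dict(self.thresholds),
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
        }


def allele_frequencies(genotypes: GenotypeMatrix) -> AlleleFrequencies:
    """p = mean(dosage)/2 over non-missing calls per marker."""
    d = genotypes.dosage
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    all_missing = np.isnan(d).all(axis=0)
    p = np.where(all_missing, np.nan, p)
    return AlleleFrequencies(p=p, all_missing=all_missing)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count of the same parity whose conditional
    probability does not exceed that of the observed configuration
    (Wigginton-style, in log space for stability).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one individual")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count (label-symmetric below)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0  # monomorphic

    # log P(het = h | allele counts) up to a shared constant:
    # P(h) proportional to rare! common! / ((rare-h)/2)! h! ((common-h)/2)! * 2^h
    # iterate over h with same parity as rare
    hets = np.arange(rare % 2, rare + 1, 2)
    lg = [
        h * math.log(2.0)
        - math.lgamma((rare - h) / 2 + 1)
        - math.lgamma(h + 1)
        - math.lgamma((2 * n - rare - h) / 2 + 1)
        for h in hets
    ]
    lg = np.array(lg)
    lg -= lg.max()
    probs = np.exp(lg)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:  # impossible parity: defensive, cannot happen with valid counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    snp_call_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    ind_call_min: float = 0.90,
    drop_sex_chromosomes: bool = True,
) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Apply the marker/individual screen in the declared order."""
    report = QcReport(
        thresholds={
            "snp_call_min": snp_call_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "ind_call_min": ind_call_min,
        },
        n_markers_in=genotypes.n_markers,
        n_individuals_in=genotypes.n_individuals,
    )
    d = genotypes.dosage
    keep_m = np.ones(genotypes.n_markers, dtype=bool)

    # 1. unmapped markers (position < 1 cannot be represented; chromosome "0"
    #    or empty is the unmapped convention)
    unmapped = np.array([str(c) in ("0", "", "nan") for c in marker_map.chromosome])
    report.removed_markers["unmapped"] = int((unmapped & keep_m).sum())
    keep_m &= ~unmapped

    # 2. sex chromosomes
    if drop_sex_chromosomes:
        sexchr = marker_map.is_sex_chromosome()
        report.removed_markers["sex_chromosome"] = int((sexchr & keep_m).sum())
        keep_m &= ~sexchr
    else:
        report.removed_markers["sex_chromosome"] = 0

    # 3. individual call rate (on currently retained markers)
    if keep_m.any():
        ind_call = 1.0 - np.isnan(d[:, keep_m]).mean(axis=1)
    else:
        ind_call = np.ones(genotypes.n_individuals)
    keep_i = ind_call >= ind_call_min
    report.removed_individuals = int((~keep_i).sum())
    d = d[keep_i]

    # 4. SNP call rate, recomputed on retained individuals
    if d.shape[0] > 0:
        call = 1.0 - np.isnan(d).mean(axis=0)
    else:
        call = np.zeros(genotypes.n_markers)
    low_call = (call < snp_call_min) & keep_m
    report.removed_markers["low_call_rate"] = int(low_call.sum())
    keep_m &= ~low_call

    # 5. MAF
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    low_maf = (~np.isfinite(maf) | (maf < maf_min)) & keep_m
    report.removed_markers["low_maf"] = int(low_maf.sum())
    keep_m &= ~low_maf

    # 6. HWE exact test
    hwe_fail = np.zeros(genotypes.n_markers, dtype=bool)
    for j in np.flatnonzero(keep_m):
        col = d[:, j]
        col = col[~np.isnan(col)]
        n_aa_ = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA_ = int((col == 2).sum())
        if n_aa_ + n_het + n_AA_ == 0:
            continue
        if hwe_exact_test(n_AA_, n_het, n_aa_) < hwe_p_min:
            hwe_fail[j] = True
    report.removed_markers["hwe_fail"] = int(hwe_fail.sum())
    keep_m &= ~hwe_fail

    ids = [iid for iid, k in zip(genotypes.individual_ids, keep_i) if k]
    out = GenotypeMatrix(d[:, keep_m].copy(), ids)
    out_map = marker_map.subset(keep_m)
    report.n_markers_out = out.n_markers
    report.n_individuals_out = out.n_individuals
    return out, out_map, report


def phenotype_outlier_filter(phenotypes: PhenotypeTable, k_sd: float = 3.0) -> PhenotypeTable:
    """Set records more than ``k_sd`` SDs from the trait mean to missing.

    Single pass per trait (mean/SD from the original non-missing values);
    values exactly at the boundary are retained (strict inequality).
    """
    data = phenotypes.data.copy()
    for t in phenotypes.trait_names:
        x = data[t].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        data.loc[(x - mu).abs() > k_sd * sd, t] = np.nan
    return PhenotypeTable(data, phenotypes.trait_names, phenotypes.factor_names)


def ld_r2(genotypes: GenotypeMatrix, marker_i: int, marker_j: int) -> float:
    """Composite (genotypic) LD: squared Pearson correlation of dosages,
    pairwise-complete observations."""
    x = genotypes.dosage[:, marker_i]
    y = genotypes.dosage[:, marker_j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    bin_width_bp: int = 10_000,
    max_dist_bp: int = 1_000_000,
    max_pairs_per_chrom: int | None = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean pairwise r^2 by distance bin (within-chromosome pairs only)."""
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    d = genotypes.dosage
    for c in pd.unique(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == c)
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = marker_map.position_bp[idx[jj]] - marker_map.position_bp[idx[ii]]
        ok = dist <= max_dist_bp
        ii, jj, dist = ii[ok], jj[ok], dist[ok]
        if max_pairs_per_chrom is not None and len(ii) > max_pairs_per_chrom:
            take = rng.choice(len(ii), size=max_pairs_per_chrom, replace=False)
            ii, jj, dist = ii[take], jj[take], dist[take]
        # standardized dosages; mean-impute missing so products stay finite
        sub = d[:, idx]
        mu = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), mu, sub)
        sub = sub - sub.mean(axis=0)
        sd = sub.std(axis=0)
        poly = sd > 0
        sub[:, poly] = sub[:, poly] / sd[poly]
        r = (sub[:, ii] * sub[:, jj]).mean(axis=0)
        r2 = np.where(poly[ii] & poly[jj], r * r, np.nan)
        bins = np.minimum(dist // bin_width_bp, n_bins - 1).astype(int)
        good = np.isfinite(r2)
        np.add.at(sums, bins[good], r2[good])
        np.add.at(counts, bins[good], 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "distance_bin_start_bp": np.arange(n_bins) * bin_width_bp,
            "distance_bin_end_bp": (np.arange(n_bins) + 1) * bin_width_bp,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
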