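"""Weighted single-step GWAS: ssGBLUP breeding values, SNP-effect
backsolving, iterative SNP reweighting, window variance decomposition and
QTL-region calling.

The iterative scheme (t = 1, D = I):

1. G_(t) = Z D_(t) Z' * lambda,  lambda = 1 / sum 2 p_i (1 - p_i)
2. GEBV for the whole pedigree by ssGBLUP (H^-1 mixed-model equations)
3. u_hat_(t) = lambda D_(t) Z' G_(t)^-1 a_hat_g
4. d_i(t+1) = u_hat_i^2 * 2 p_i (1 - p_i)
5. normalize d so the trace stays at the SNP count
6. rebuild G and loop to 2

The percentage of genetic variance of a 20-SNP sliding window is the
empirical variance (across genotyped individuals) of the window's genomic
value sum(z_j u_hat_j), divided by sigma2_a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import GeneAnnotation, GenotypeMatrix, MarkerMap, PedigreeTable, PhenotypeTable
from .genotype_qc import AlleleFrequencies, allele_frequencies
from .relationships import (
    GenomicMatrix,
    HInverse,
    a_inverse,
    genomic_relationship,
    h_inverse,
    numerator_relationship,
    subset_a22,
    tune_and_blend,
)
from .variance_components import ModelSpec, VarianceComponents, build_design

__all__ = [
    "MmeSolution",
    "SnpEffectState",
    "solve_mme",
    "backsolve_snp_effects",
    "update_weights",
    "normalize_weights",
    "run_wssgwas",
    "window_variances",
    "top_windows",
    "top_percent_snps",
]


@dataclass
class MmeSolution:
    """Solution of Henderson's mixed-model equations."""

    beta: np.ndarray
    beta_names: list[str]
    breeding_values: pd.Series  # indexed by animal id, all pedigree animals
    variance_ratio: float
    residual_ratio: float  # ||C s - rhs|| / ||rhs||

    def gebv_of(self, ids: list[str]) -> np.ndarray:
        return self.breeding_values.reindex(ids).to_numpy()


@dataclass
class SnpEffectState:
    """Per-iteration SNP effects and weights of the reweighting loop."""

    iteration: int
    u_hat: np.ndarray
    weights: np.ndarray
    lam: float
    p: np.ndarray
    centered_z: np.ndarray
    history: list[dict] = field(default_factory=list)


def solve_mme(
    model: ModelSpec,
    phenotypes: PhenotypeTable,
    h_inv: HInverse | sp.spmatrix,
    vc: VarianceComponents,
    animals: list[str] | None = None,
) -> MmeSolution:
    """Solve the single-trait MME with variance ratio sigma2_e/sigma2_a on
    the additive block; animals without records get breeding values through
    the relationships."""
    if vc.sigma2_a <= 0 or vc.sigma2_e <= 0:
        raise ValueError("variance components must be strictly positive")
    if isinstance(h_inv, HInverse):
        kinv = h_inv.matrix
        animals = h_inv.animals
    else:
        kinv = sp.csr_matrix(h_inv)
        if animals is None:
            raise ValueError("animal id list required with a bare sparse inverse")
    trait = model.traits[0]
    data = phenotypes.data.loc[phenotypes.data[trait].notna()].reset_index(drop=True)
    x, names = build_design(data, model.factors)
    y = data[trait].to_numpy(dtype=np.float64)
    pos = {a: i for i, a in enumerate(animals)}
    try:
        rec_animal = np.array([pos[a] for a in data["animal"]], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"phenotyped animal {exc.args[0]!r} missing from relationship") from None

    n_a = len(animals)
    p = x.shape[1]
    ratio = vc.sigma2_e / vc.sigma2_a
    w = sp.coo_matrix(
        (np.ones(len(y)), (np.arange(len(y)), rec_animal)), shape=(len(y), n_a)
    ).tocsr()

    xtx = x.T @ x
    xtw = x.T @ w
    wtw = (w.T @ w).toarray()
    c = np.zeros((p + n_a, p + n_a))
    c[:p, :p] = xtx
    c[:p, p:] = xtw
    c[p:, :p] = xtw.T
    c[p:, p:] = wtw + ratio * kinv.toarray()
    rhs = np.concatenate([x.T @ y, w.T @ y])
    try:
        sol = np.linalg.solve(c, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular MME coefficient matrix; check for confounded levels of {model.factors}"
        ) from exc
    resid = float(np.linalg.norm(c @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return MmeSolution(
        beta=sol[:p],
        beta_names=names,
        breeding_values=pd.Series(sol[p:], index=list(animals)),
        variance_ratio=ratio,
        residual_ratio=resid,
    )


def backsolve_snp_effects(
    genomic: GenomicMatrix,
    a_g: np.ndarray,
    g_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """u_hat = lambda D Z' G^-1 a_hat_g.

    ``g_matrix`` defaults to the raw G of ``genomic``; pass the
    tuned/blended matrix to backsolve against the G actually used in H."""
    g = genomic.values if g_matrix is None else g_matrix
    if g.shape[0] != len(a_g):
        raise ValueError("GEBV vector does not match the genomic matrix dimension")
    ginv_a = np.linalg.solve(g, np.asarray(a_g, dtype=np.float64))
    return genomic.lam * genomic.weights * (genomic.centered_z.T @ ginv_a)


def update_weights(u_hat: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d_i = u_hat_i^2 * 2 p_i (1 - p_i)."""
    p = np.where(np.isfinite(p), p, 0.0)
    return np.asarray(u_hat) ** 2 * 2.0 * p * (1.0 - p)


def normalize_weights(d: np.ndarray, m: int | None = None) -> np.ndarray:
    """Rescale so the trace equals the SNP count (total variance constant)."""
    d = np.asarray(d, dtype=np.float64)
    if m is None:
        m = len(d)
    total = d.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero SNP weights")
    return d * (m / total)


def run_wssgwas(
    model: ModelSpec,
    phenotypes: PhenotypeTable,
    pedigree: PedigreeTable,
    genotypes: GenotypeMatrix,
    vc: VarianceComponents,
    n_reweight: int = 1,
    blend_weight: float = 0.95,
    freqs: AlleleFrequencies | None = None,
) -> tuple[SnpEffectState, MmeSolution]:
    """Run the reweighting loop; ``n_reweight`` counts executions of the
    weight-update steps (0 = plain unweighted ssGBLUP)."""
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    m = genotypes.n_markers
    a_mat = numerator_relationship(pedigree)
    a_inv = a_inverse(pedigree, a_mat.inbreeding)
    a22 = subset_a22(a_mat, genotypes.individual_ids)

    d = np.ones(m)
    history: list[dict] = []
    state = None
    solution = None
    genomic = None
    for t in range(1, n_reweight + 2):
        genomic = genomic_relationship(genotypes, freqs, weights=d)
        g_w, alpha, beta = tune_and_blend(genomic, a22, blend_weight=blend_weight)
        hinv = h_inverse(a_inv, a22, g_w, genotypes.individual_ids, pedigree.animals)
        solution = solve_mme(model, phenotypes, hinv, vc)
        a_g = solution.gebv_of(genotypes.individual_ids)
        u_hat = backsolve_snp_effects(genomic, a_g, g_matrix=g_w)
        history.append({"iteration": t, "weights": d.copy(), "u_hat": u_hat.copy()})
        if t <= n_reweight:
            d = normalize_weights(update_weights(u_hat, freqs.p), m)
    state = SnpEffectState(
        iteration=n_reweight + 1,
        u_hat=history[-1]["u_hat"],
        weights=history[-1]["weights"],
        lam=genomic.lam,
        p=freqs.p,
        centered_z=genomic.centered_z,
        history=history,
    )
    return state, solution


# ---------------------------------------------------------------------------
# window variance decomposition and QTL calling
# ---------------------------------------------------------------------------


def window_variances(
    state: SnpEffectState,
    marker_map: MarkerMap,
    vc: VarianceComponents,
    window_size: int = 20,
) -> pd.DataFrame:
    """Sliding windows (step 1 SNP) of ``window_size`` consecutive SNPs:
    pct = var_individuals(sum_j z_j u_hat_j) / sigma2_a * 100.

    Chromosomes with fewer SNPs than the window yield one truncated,
    flagged window; truncated windows are excluded from ranking."""
    if state.centered_z.shape[1] != len(marker_map):
        raise ValueError("marker map does not match the SNP-effect state")
    zm = state.centered_z * state.u_hat  # per-SNP genomic values
    rows = []
    for c in pd.unique(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == c)
        mc = len(idx)
        block = zm[:, idx]
        cs = np.cumsum(block, axis=1)
        if mc < window_size:
            val = cs[:, -1]
            rows.append((c, idx[0], idx[-1], marker_map.position_bp[idx[0]],
                         marker_map.position_bp[idx[-1]], float(np.var(val, ddof=1)), True))
            continue
        for j in range(mc - window_size + 1):
            hi = j + window_size - 1
            val = cs[:, hi] - (cs[:, j - 1] if j > 0 else 0.0)
            rows.append(
                (
                    c,
                    idx[j],
                    idx[hi],
                    marker_map.position_bp[idx[j]],
                    marker_map.position_bp[idx[hi]],
                    float(np.var(val, ddof=1)),
                    False,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["chromosome", "first_snp", "last_snp", "start_bp", "end_bp", "var_window", "truncated"],
    )
    df["pct_variance"] = df["var_window"] / vc.sigma2_a * 100.0
    df = df.drop(columns=["var_window"])
    ranked = df.loc[~df["truncated"]].sort_values(
        by=["pct_variance", "chromosome", "start_bp"], ascending=[False, True, True]
    )
    df["rank"] = pd.NA
    df.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
    return df


def top_windows(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Call the top-k QTL regions from ranked windows.

    Windows are visited in rank order (pct descending, ties by chromosome
    then start).  A window overlapping or book-ended adjacent to an
    already-called region merges into it (extends the span); otherwise it
    seeds a new region while fewer than k exist.  Scanning stops at the
    first window that can do neither.  With step-1 sliding windows the
    highest-ranked windows are neighbours of the same peak, so distinct
    merged regions - not raw windows - are the meaningful QTL calls."""
    if results.empty:
        raise ValueError("no windows to rank")
    ranked = results.loc[results["rank"].notna()].sort_values("rank")
    regions: list[dict] = []
    for _, w in ranked.iterrows():
        merged = False
        for cur in regions:
            if (
                cur["chromosome"] == w["chromosome"]
                and w["start_bp"] <= cur["end_bp"] + 1
                and w["end_bp"] >= cur["start_bp"] - 1
            ):
                cur["start_bp"] = min(cur["start_bp"], int(w["start_bp"]))
                cur["end_bp"] = max(cur["end_bp"], int(w["end_bp"]))
                cur["n_windows"] += 1
                cur["sum_pct_variance"] += float(w["pct_variance"])
                cur["best_rank"] = min(cur["best_rank"], int(w["rank"]))
                merged = True
                break
        if merged:
            continue
        if len(regions) < k:
            regions.append(
                {
                    "chromosome": w["chromosome"],
                    "start_bp": int(w["start_bp"]),
                    "end_bp": int(w["end_bp"]),
                    "n_windows": 1,
                    "sum_pct_variance": float(w["pct_variance"]),
                    "best_rank": int(w["rank"]),
                }
            )
        else:
            break
    out = pd.DataFrame(regions).sort_values("best_rank").reset_index(drop=True)
    return out


def top_percent_snps(
    results: pd.DataFrame,
    annotation: GeneAnnotation,
    fraction: float = 0.01,
) -> list[str]:
    """Genes overlapping the top ceil(fraction * n_windows) ranked windows."""
    ranked = results.loc[results["rank"].notna()].sort_values("rank")
    n_top = math.ceil(fraction * len(ranked))
    sel = ranked.head(n_top)
    if len(annotation) == 0:
        return []
    genes = annotation.table
    hits: set[str] = set()
    for c, grp in sel.groupby("chromosome", sort=False):
        sub = genes.loc[genes["chromosome"].astype(str) == str(c)]
        if sub.empty:
            continue
        for _, w in grp.iterrows():
            ov = (sub["start_bp"] <= w["end_bp"]) & (sub["end_bp"] >= w["start_bp"])
            hits.update(sub.loc[ov, "gene_id"].tolist())
    return sorted(hits)
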