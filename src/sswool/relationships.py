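"""Relationship matrices for single-step evaluation.

Covers the pedigree numerator relationship matrix A (tabular method with
inbreeding), its sparse inverse by Henderson's rules with inbreeding
(Quaas), the genotyped-animal submatrix A22, the (optionally weighted)
VanRaden genomic matrix G = Z D Z' / sum(2 p (1-p)), two-moment tuning and
blending of G against A22, and the single-step inverse

    H^-1 = A^-1 + [[0, 0], [0, Gw^-1 - A22^-1]].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data_io import GenotypeMatrix, PedigreeTable
from .genotype_qc import AlleleFrequencies

__all__ = [
    "NumeratorMatrix",
    "GenomicMatrix",
    "HInverse",
    "numerator_relationship",
    "a_inverse",
    "subset_a22",
    "genomic_relationship",
    "tune_and_blend",
    "h_inverse",
    "safe_inverse",
]

log = logging.getLogger(__name__)


@dataclass
class NumeratorMatrix:
    """Dense A over all pedigree animals plus per-animal inbreeding F."""

    values: np.ndarray
    animals: list[str]

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


@dataclass
class GenomicMatrix:
    """G = Z D Z' * lambda with Z centered by 2p; lambda = 1/sum 2p(1-p)."""

    values: np.ndarray
    individual_ids: list[str]
    centered_z: np.ndarray
    weights: np.ndarray
    lam: float


@dataclass
class HInverse:
    """A^-1 plus the genotyped-block correction, over all pedigree animals."""

    matrix: sp.csr_matrix
    animals: list[str]
    genotyped_index: np.ndarray  # positions of genotyped animals in `animals`

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def numerator_relationship(pedigree: PedigreeTable) -> NumeratorMatrix:
    """Tabular (recursive) A with inbreeding: a(i,i) = 1 + a(s,d)/2."""
    n = len(pedigree)
    a = np.zeros((n, n))
    s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        si, di = s_idx[i], d_idx[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * a[si, :i]
        if di >= 0:
            row += 0.5 * a[di, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    return NumeratorMatrix(a, list(pedigree.animals))


def a_inverse(pedigree: PedigreeTable, inbreeding: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding (Quaas).

    Per-animal Mendelian-sampling variance d_i = 0.5 - 0.25 (F_s + F_d),
    with 0.25(1 + F_p) restored per unknown parent; contribution block
    alpha_i * w w' with w = (1, -0.5 per known parent).
    """
    n = len(pedigree)
    if inbreeding is None:
        inbreeding = numerator_relationship(pedigree).inbreeding
    f = np.asarray(inbreeding, dtype=np.float64)
    rows, cols, vals = [], [], []
    s_idx, d_idx = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        parents = [p for p in (s_idx[i], d_idx[i]) if p >= 0]
        d_i = 1.0 - sum(0.25 * (1.0 + f[p]) for p in parents)
        alpha = 1.0 / d_i
        members = [i] + parents
        coefs = [1.0] + [-0.5] * len(parents)
        for a_m, a_c in zip(members, coefs):
            for b_m, b_c in zip(members, coefs):
                rows.append(a_m)
                cols.append(b_m)
                vals.append(alpha * a_c * b_c)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def subset_a22(a: NumeratorMatrix, genotyped_ids: list[str]) -> np.ndarray:
    """Principal submatrix of A in the order of ``genotyped_ids``."""
    pos = {aid: i for i, aid in enumerate(a.animals)}
    try:
        idx = np.array([pos[g] for g in genotyped_ids], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"genotyped id {exc.args[0]!r} not in pedigree") from None
    return a.values[np.ix_(idx, idx)]


def genomic_relationship(
    genotypes: GenotypeMatrix,
    freqs: AlleleFrequencies,
    weights: np.ndarray | None = None,
) -> GenomicMatrix:
    """VanRaden genomic relationship matrix, optionally SNP-weighted.

    Missing dosages are mean-imputed to 2p before centering (zero
    contribution to relationships); monomorphic markers (p in {0, 1} or no
    calls) are excluded from both Z and the lambda scale.
    """
    p = np.asarray(freqs.p, dtype=np.float64)
    if weights is None:
        weights = np.ones_like(p)
    weights = np.asarray(weights, dtype=np.float64)
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("no polymorphic markers: sum 2p(1-p) is zero")
    p_k = p[keep]
    d = genotypes.dosage[:, keep]
    d = np.where(np.isnan(d), 2.0 * p_k, d)
    z = d - 2.0 * p_k
    het = 2.0 * p_k * (1.0 - p_k)
    lam = 1.0 / het.sum()
    w = weights[keep]
    g = (z * w) @ z.T * lam
    full_z = np.zeros_like(genotypes.dosage)
    full_z[:, keep] = z
    return GenomicMatrix(
        values=g,
        individual_ids=list(genotypes.individual_ids),
        centered_z=full_z,
        weights=np.where(keep, weights, 0.0),
        lam=lam,
    )


def safe_inverse(mat: np.ndarray, jitter: float = 1e-8, name: str = "matrix") -> np.ndarray:
    """Symmetric inverse via Cholesky, retrying once with a diagonal jitter."""
    mat = np.asarray(mat, dtype=np.float64)
    sym = 0.5 * (mat + mat.T)
    try:
        c = np.linalg.cholesky(sym)
    except np.linalg.LinAlgError:
        log.warning("%s not positive definite; adding %g jitter to diagonal", name, jitter)
        try:
            c = np.linalg.cholesky(sym + jitter * np.eye(len(sym)))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"{name} is not invertible (even with jitter)") from exc
    ident = np.eye(len(sym))
    inv_c = np.linalg.solve(c, ident)
    return inv_c.T @ inv_c


def tune_and_blend(
    g: GenomicMatrix | np.ndarray,
    a22: np.ndarray,
    blend_weight: float = 0.95,
) -> tuple[np.ndarray, float, float]:
    """Two-moment tuning of G to A22, then blending for invertibility.

    Solves alpha + beta * mean(diag G) = mean(diag A22) and likewise for the
    off-diagonal means, then returns
    Gw = blend_weight * (alpha + beta G) + (1 - blend_weight) * A22,
    plus the fitted (alpha, beta).  beta is the weighting factor matching
    the average diagonals of G and A22.
    """
    gv = g.values if isinstance(g, GenomicMatrix) else np.asarray(g, dtype=np.float64)
    if gv.shape != a22.shape:
        raise ValueError("G and A22 are not conformable")
    n = gv.shape[0]
    dg, da = np.diag(gv).mean(), np.diag(a22).mean()
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        og, oa = gv[off].mean(), a22[off].mean()
        denom = dg - og
        if abs(denom) < 1e-12:
            beta, alpha = 1.0, da - dg
        else:
            beta = (da - oa) / denom
            alpha = oa - beta * og
    else:
        beta, alpha = 1.0, da - dg
    if beta <= 0:
        raise ValueError(f"tuning produced non-positive scale beta={beta:.4g}")
    gw = blend_weight * (alpha + beta * gv) + (1.0 - blend_weight) * a22
    # fail fast if the blended matrix is still singular
    sign, _ = np.linalg.slogdet(gw)
    if sign <= 0:
        eigmin = float(np.linalg.eigvalsh(gw).min())
        if eigmin <= 0:
            raise np.linalg.LinAlgError(
                f"blended genomic matrix not invertible (min eigenvalue {eigmin:.3g})"
            )
    return gw, float(alpha), float(beta)


def h_inverse(
    a_inv: sp.spmatrix,
    a22: np.ndarray,
    g_w: np.ndarray,
    genotyped_ids: list[str],
    animals: list[str],
) -> HInverse:
    """Assemble H^-1 = A^-1 + [[0,0],[0, Gw^-1 - A22^-1]] on genotyped rows."""
    pos = {a: i for i, a in enumerate(animals)}
    idx = np.array([pos[g] for g in genotyped_ids], dtype=np.int64)
    h = sp.lil_matrix(a_inv.tocsr(), dtype=np.float64)
    if len(idx) > 0:
        gw_inv = safe_inverse(g_w, name="blended G")
        a22_inv = safe_inverse(a22, name="A22")
        corr = gw_inv - a22_inv
        h[np.ix_(idx, idx)] = h[np.ix_(idx, idx)].toarray() + corr
    return HInverse(matrix=h.tocsr(), animals=list(animals), genotyped_index=idx)
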