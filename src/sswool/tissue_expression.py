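"""Tissue-specificity scoring from a multi-tissue expression atlas.

Per gene and target tissue (or organ system) a least-squares model

    y = mu + x beta + (age, sex covariates) + e

is fitted, where y is the per-gene z-scaled log2(TPM + 0.25) profile and x
codes samples of the target +1 and samples outside its organ system -1
(same-system non-target samples are excluded when the target is a tissue).
Genes are ranked by t = beta / SE; the top decile defines the
tissue-specific gene set.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, SampleMetadata

__all__ = [
    "tpm_normalize",
    "scale_expression",
    "fit_tissue_model",
    "fit_tissue_models",
    "tissue_specific_genes",
    "sample_correlation_matrix",
]

log = logging.getLogger(__name__)

SE_FLOOR = 1e-12
PSEUDOCOUNT = 0.25


def tpm_normalize(counts: np.ndarray, lengths_bp: np.ndarray, gene_ids: list[str], sample_ids: list[str]) -> ExpressionMatrix:
    """Counts -> TPM: rate = counts / length_kb, scaled to 1e6 per sample."""
    lengths_bp = np.asarray(lengths_bp, dtype=np.float64)
    if np.any(lengths_bp <= 0):
        raise ValueError("gene lengths must be positive")
    rate = np.asarray(counts, dtype=np.float64) / (lengths_bp[:, None] / 1000.0)
    total = rate.sum(axis=0)
    if np.any(total <= 0):
        bad = [sample_ids[j] for j in np.flatnonzero(total <= 0)]
        raise ValueError(f"all-zero samples cannot be TPM-normalized: {bad[:5]}")
    return ExpressionMatrix(rate / total * 1e6, gene_ids, sample_ids)


def scale_expression(tpm: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """log2(TPM + 0.25), then per-gene z-scaling across samples.

    Returns the scaled matrix and the gene ids retained (zero-variance
    genes are excluded and logged)."""
    y = np.log2(tpm.values + PSEUDOCOUNT)
    sd = y.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.info("scale_expression: excluding %d zero-variance genes", (~keep).sum())
    y = y[keep]
    y = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, ddof=0, keepdims=True)
    genes = [g for g, k in zip(tpm.gene_ids, keep) if k]
    return y, genes


def _design_for_target(metadata: SampleMetadata, target: str) -> tuple[np.ndarray, np.ndarray]:
    """Sample mask and design matrix (intercept, +1/-1 code, covariates)."""
    t = metadata.table
    tissues = set(t["tissue"])
    systems = set(t["organ_system"])
    if target in tissues:
        system = metadata.organ_system_of(target)
        in_target = (t["tissue"] == target).to_numpy()
        same_system_other = ((t["organ_system"] == system) & ~in_target).to_numpy()
        mask = ~same_system_other
    elif target in systems:
        in_target = (t["organ_system"] == target).to_numpy()
        mask = np.ones(len(t), dtype=bool)
    else:
        raise KeyError(f"{target!r} is neither a tissue nor an organ system")
    code = np.where(in_target, 1.0, -1.0)[mask]
    if (code > 0).sum() < 2 or (code < 0).sum() < 2:
        raise ValueError(f"target {target!r}: need >= 2 samples on each side of the contrast")
    sub = t.loc[mask]
    cols = [np.ones(mask.sum()), code]
    for covar in ("age_stage", "sex"):
        d = pd.get_dummies(sub[covar].astype(str), dtype=float)
        d = d.reindex(sorted(d.columns), axis=1).iloc[:, 1:]  # drop-first coding
        for c in d.columns:
            cols.append(d[c].to_numpy())
    x = np.column_stack(cols)
    # drop collinear covariate columns (keep intercept + code), refit design
    q = np.linalg.qr(x, mode="r")
    keep_cols = np.abs(np.diag(q)) > 1e-10 * max(1.0, np.abs(np.diag(q)).max())
    if not keep_cols.all():
        log.warning("target %s: dropping %d collinear covariate columns", target, (~keep_cols).sum())
        keep_cols[:2] = True
        x = x[:, keep_cols]
    return mask, x


def fit_tissue_models(
    scaled: np.ndarray,
    gene_ids: list[str],
    metadata: SampleMetadata,
    target: str,
) -> pd.DataFrame:
    """Least-squares tissue-effect fit for every gene at once.

    Returns a DataFrame (gene_id, beta, se, t, rank) ranked by t
    descending, ties broken by gene id."""
    mask, x = _design_for_target(metadata, target)
    y = scaled[:, mask]  # genes x samples
    n, p = x.shape
    if n <= p:
        raise ValueError(f"target {target!r}: {n} samples cannot identify {p} parameters")
    xtx_inv = np.linalg.inv(x.T @ x)
    betas = y @ x @ xtx_inv.T  # genes x p
    resid = y - betas @ x.T
    dof = n - p
    s2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(s2 * xtx_inv[1, 1], 0.0))
    se = np.maximum(se, SE_FLOOR)
    beta = betas[:, 1]
    t = beta / se
    out = pd.DataFrame({"gene_id": gene_ids, "beta": beta, "se": se, "t": t})
    out = out.sort_values(["t", "gene_id"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def fit_tissue_model(
    y: np.ndarray,
    gene_id: str,
    metadata: SampleMetadata,
    target: str,
) -> tuple[float, float, float]:
    """Single-gene convenience wrapper: returns (beta, se, t)."""
    res = fit_tissue_models(np.atleast_2d(y), [gene_id], metadata, target)
    row = res.iloc[0]
    return float(row["beta"]), float(row["se"]), float(row["t"])


def tissue_specific_genes(results: pd.DataFrame, fraction: float = 0.10) -> list[str]:
    """Top floor(fraction * n) genes by t (descending; ties by gene id)."""
    if results.empty:
        log.warning("tissue_specific_genes: empty result set")
        return []
    n = math.floor(fraction * len(results))
    ordered = results.sort_values(["t", "gene_id"], ascending=[False, True])
    return ordered["gene_id"].head(n).tolist()


def sample_correlation_matrix(scaled: np.ndarray) -> np.ndarray:
    """Pearson correlations between sample columns (unit diagonal)."""
    if scaled.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    c = np.corrcoef(scaled, rowvar=False)
    np.fill_diagonal(c, 1.0)
    return c
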