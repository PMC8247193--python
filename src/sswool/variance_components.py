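"""REML variance components under the animal model.

Model: y = X beta + Z a + e with a ~ N(0, K sigma2_a) and e ~ N(0, I
sigma2_e), where K is the relationship matrix restricted to recorded
animals (pedigree A or the single-step H).  Fitting is average-information
REML computed in the eigenbasis of K — an exact reparametrization that
makes every iteration O(n p^2) after one symmetric eigendecomposition —
with damped steps and PSD projection whenever a raw AI step leaves the
parameter space.  Standard errors come from the inverse of the final
average-information matrix; h2 and r_g standard errors by the delta
method.

Bivariate fits use animals with records on both traits (pairwise-complete)
and parametrize (a11, a12, a22, e11, e12, e22).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .data_io import PhenotypeTable

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "REMLResult",
    "build_design",
    "reml_loglik",
    "reml_fit",
    "heritability",
    "genetic_correlation",
]


@dataclass
class ModelSpec:
    traits: list[str]
    factors: list[str] = field(default_factory=lambda: ["flock", "birth_year", "season"])
    relationship_source: str = "pedigree_A"  # or "h_matrix"


@dataclass
class VarianceComponents:
    """(Co)variance estimates; matrices are t x t over ``traits``.

    ``sampling_cov`` rows/columns follow ``param_names``: for a single
    trait (sigma2_a, sigma2_e); for a pair
    (a11, a12, a22, e11, e12, e22)."""

    traits: list[str]
    sigma_a: np.ndarray
    sigma_e: np.ndarray
    sampling_cov: np.ndarray | None = None

    @property
    def param_names(self) -> list[str]:
        if len(self.traits) == 1:
            return ["sigma2_a", "sigma2_e"]
        return ["a11", "a12", "a22", "e11", "e12", "e22"]

    @property
    def sigma2_a(self) -> float:
        return float(self.sigma_a[0, 0])

    @property
    def sigma2_e(self) -> float:
        return float(self.sigma_e[0, 0])

    @property
    def cov_a(self) -> float:
        return float(self.sigma_a[0, 1])

    @property
    def cov_e(self) -> float:
        return float(self.sigma_e[0, 1])


@dataclass
class REMLResult:
    vc: VarianceComponents
    h2: dict[str, float]
    h2_se: dict[str, float]
    r_g: float | None
    r_g_se: float | None
    r_p: float | None
    loglik: float
    converged: bool
    n_iterations: int
    gradient_norm: float


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def build_design(data: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effect design; the first factor carries the
    full set of level indicators (absorbing the intercept), later factors
    drop their first level."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    if not factors:
        return np.ones((len(data), 1)), ["intercept"]
    for k, f in enumerate(factors):
        dummies = pd.get_dummies(data[f].astype(str), prefix=f, dtype=float)
        dummies = dummies.reindex(sorted(dummies.columns), axis=1)
        if k > 0:
            dummies = dummies.iloc[:, 1:]
        cols.append(dummies.to_numpy())
        names.extend(dummies.columns.tolist())
    x = np.hstack(cols) if cols else np.ones((len(data), 1))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient ({rank} < {x.shape[1]}); "
            f"confounded levels among {factors}"
        )
    return x, names


# ---------------------------------------------------------------------------
# restricted log-likelihood (dense; the grid-search oracle)
# ---------------------------------------------------------------------------


def reml_loglik(
    sigma2_a: float,
    sigma2_e: float,
    y: np.ndarray,
    x: np.ndarray,
    k: np.ndarray,
) -> float:
    """Restricted log-likelihood, constant convention
    -0.5 [log|V| + log|X'V^-1 X| + y'Py], computed densely."""
    if sigma2_a < 0 or sigma2_e <= 0:
        return -np.inf
    n = len(y)
    v = sigma2_a * k + sigma2_e * np.eye(n)
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    vi_y = scipy.linalg.cho_solve((c, True), y)
    vi_x = scipy.linalg.cho_solve((c, True), x)
    xtvix = x.T @ vi_x
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvix, x.T @ vi_y)
    ypy = float(y @ vi_y - (x.T @ vi_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + ypy)


# ---------------------------------------------------------------------------
# single-trait AI-REML in the eigenbasis of K
# ---------------------------------------------------------------------------


def _eigen_rotate(k: np.ndarray, y: np.ndarray, x: np.ndarray):
    w, u = scipy.linalg.eigh(0.5 * (k + k.T))
    w = np.clip(w, 0.0, None)
    return w, u.T @ y, u.T @ x


def _single_core(theta, lam, yt, xt):
    """Loglik, gradient, AI matrix and beta for theta = (s2a, s2e)."""
    s2a, s2e = theta
    v = s2a * lam + s2e
    vi = 1.0 / v
    wx = xt * vi[:, None]
    xtvix = xt.T @ wx
    cmat = np.linalg.inv(xtvix)
    beta = cmat @ (wx.T @ yt)
    r = yt - xt @ beta
    py = r * vi
    logdet_v = np.log(v).sum()
    sign, logdet_x = np.linalg.slogdet(xtvix)
    ll = -0.5 * (logdet_v + logdet_x + float(r @ py))

    grads = np.empty(2)
    qs = []
    for i, dv in enumerate((lam, np.ones_like(lam))):
        tr_vinv = float((dv * vi).sum())
        m = xt.T @ (xt * (dv * vi * vi)[:, None])
        tr_corr = float(np.trace(cmat @ m))
        ypvp = float(((py * py) * dv).sum())
        grads[i] = -0.5 * ((tr_vinv - tr_corr) - ypvp)
        qs.append(dv * py)

    def apply_p(q):
        return q * vi - wx @ (cmat @ (wx.T @ q))

    ai = np.empty((2, 2))
    pq = [apply_p(q) for q in qs]
    for i in range(2):
        for j in range(2):
            ai[i, j] = 0.5 * float(qs[i] @ pq[j])
    return ll, grads, ai, beta


def _fit_single(
    y: np.ndarray,
    x: np.ndarray,
    k: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    lam, yt, xt = _eigen_rotate(k, y, x)
    vary = float(np.var(y, ddof=1))
    floor = max(vary, 1e-12) * 1e-8
    theta = np.array([0.5 * vary, 0.5 * vary])
    ll, grads, ai, _ = _single_core(theta, lam, yt, xt)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(ai + 1e-12 * np.eye(2), grads)
        except np.linalg.LinAlgError:
            step = grads * theta**2 / len(y)  # EM-flavoured gradient step
        new = theta + step
        halvings = 0
        while (new[0] < 0 or new[1] <= 0) and halvings < 30:
            step *= 0.5
            new = theta + step
            halvings += 1
        new = np.maximum(new, [0.0, floor])
        new[0] = max(new[0], 0.0)
        ll_new, grads_new, ai_new, _ = _single_core(np.maximum(new, [floor, floor]), lam, yt, xt)
        rel = np.max(np.abs(new - theta) / (np.abs(theta) + vary * 1e-6))
        theta, ll, grads, ai = new, ll_new, grads_new, ai_new
        if rel < tol or np.linalg.norm(grads) < tol * len(y):
            converged = True
            break
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return theta, cov, ll, converged, it, float(np.linalg.norm(grads))


# ---------------------------------------------------------------------------
# bivariate AI-REML in the eigenbasis of K
# ---------------------------------------------------------------------------

_BASIS = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
]


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sa = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    se = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return sa, se


def _pack(sa: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.array([sa[0, 0], sa[0, 1], sa[1, 1], se[0, 0], se[0, 1], se[1, 1]])


def _project_psd(m: np.ndarray, floor: float) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    return v @ np.diag(np.clip(w, floor, None)) @ v.T


def _bi_accumulate(xt: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Assemble the 2p x 2p matrix with (t,t') block X' diag(w[t,t']) X."""
    p = xt.shape[1]
    out = np.empty((2 * p, 2 * p))
    for t in range(2):
        for s in range(2):
            out[t * p : (t + 1) * p, s * p : (s + 1) * p] = xt.T @ (xt * w[:, t, s][:, None])
    return out


def _bi_core(theta, lam, yt, xt):
    """Loglik, gradient, AI matrix for the 6-parameter bivariate model."""
    sa, se = _unpack(theta)
    n, p = xt.shape
    # per-component 2x2 covariances V_k = lam_k Sa + Se and inverses
    v = lam[:, None, None] * sa[None] + se[None]
    det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(v[:, 0, 0] <= 0) or np.any(v[:, 1, 1] <= 0):
        return None
    vi = np.empty_like(v)
    vi[:, 0, 0] = v[:, 1, 1] / det
    vi[:, 1, 1] = v[:, 0, 0] / det
    vi[:, 0, 1] = vi[:, 1, 0] = -v[:, 0, 1] / det

    xtvix = _bi_accumulate(xt, vi)
    try:
        cmat = np.linalg.inv(xtvix)
    except np.linalg.LinAlgError:
        return None
    # rhs: X' V^-1 y, stacked by trait
    viy = np.einsum("kts,ks->kt", vi, yt)
    rhs = np.concatenate([xt.T @ viy[:, 0], xt.T @ viy[:, 1]])
    beta = cmat @ rhs
    mean = np.stack([xt @ beta[:p], xt @ beta[p:]], axis=1)
    r = yt - mean
    py = np.einsum("kts,ks->kt", vi, r)

    logdet_v = float(np.log(det).sum())
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return None
    ll = -0.5 * (logdet_v + logdet_x + float((r * py).sum()))

    # derivative structures: dV_k = c_k * E for E in basis, c = lam (additive)
    # or 1 (residual)
    scales = [lam, lam, lam, np.ones_like(lam), np.ones_like(lam), np.ones_like(lam)]
    bases = _BASIS + _BASIS
    grads = np.empty(6)
    qs = []
    for i in range(6):
        e = bases[i]
        c = scales[i]
        # tr(V^-1 dV) = c_k * tr(vi_k E)
        tr_vinv = float((c * np.einsum("kts,st->k", vi, e)).sum())
        # W2_k = vi dV vi  (2x2 per k), then trace correction via C
        w2 = np.einsum("kab,bc,kcd->kad", vi, e, vi) * c[:, None, None]
        m = _bi_accumulate(xt, w2)
        tr_corr = float(np.trace(cmat @ m))
        q = np.einsum("ts,ks->kt", e, py) * c[:, None]
        ypvp = float((py * q).sum())
        grads[i] = -0.5 * ((tr_vinv - tr_corr) - ypvp)
        qs.append(q)

    def apply_p(q):
        viq = np.einsum("kts,ks->kt", vi, q)
        xviq = np.concatenate([xt.T @ viq[:, 0], xt.T @ viq[:, 1]])
        u = cmat @ xviq
        xu = np.stack([xt @ u[:p], xt @ u[p:]], axis=1)
        return viq - np.einsum("kts,ks->kt", vi, xu)

    pq = [apply_p(q) for q in qs]
    ai = np.empty((6, 6))
    for i in range(6):
        for j in range(6):
            ai[i, j] = 0.5 * float((qs[i] * pq[j]).sum())
    return ll, grads, ai


def _fit_bivariate(
    y: np.ndarray,  # n x 2
    x: np.ndarray,
    k: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    lam, yt, xt = _eigen_rotate(k, y, x)
    v1, v2 = np.var(y[:, 0], ddof=1), np.var(y[:, 1], ddof=1)
    floor = 1e-8 * max(v1, v2, 1e-12)
    sa = 0.5 * np.array([[v1, 0.0], [0.0, v2]])
    se = sa.copy()
    theta = _pack(sa, se)
    core = _bi_core(theta, lam, yt, xt)
    if core is None:
        raise RuntimeError("bivariate REML: invalid starting values")
    ll, grads, ai = core
    converged = False
    it = 0
    scale = max(v1, v2)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(ai + 1e-12 * np.eye(6), grads)
        except np.linalg.LinAlgError:
            step = grads * (theta**2 + floor) / len(y)
        new = theta + step
        ok = None
        for _ in range(30):
            sa_n, se_n = _unpack(new)
            sa_n = _project_psd(sa_n, 0.0)
            se_n = _project_psd(se_n, floor)
            cand = _pack(sa_n, se_n)
            ok = _bi_core(np.maximum(cand, -np.inf), lam, yt, xt) if np.all(np.isfinite(cand)) else None
            if ok is not None:
                new = cand
                break
            step *= 0.5
            new = theta + step
        if ok is None:  # total failure: keep previous iterate
            break
        rel = np.max(np.abs(new - theta) / (np.abs(theta) + scale * 1e-6))
        theta, (ll, grads, ai) = new, ok
        if rel < tol or np.linalg.norm(grads) < tol * len(y):
            converged = True
            break
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((6, 6), np.nan)
    return theta, cov, ll, converged, it, float(np.linalg.norm(grads))


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def _relationship_submatrix(
    relationship: np.ndarray | sp.spmatrix,
    relationship_ids: list[str],
    animals: list[str],
    is_inverse: bool = False,
) -> np.ndarray:
    """K restricted to ``animals``; inverts first when handed K^-1
    (e.g. a sparse H^-1), since the submatrix of the inverse is not the
    inverse of the submatrix."""
    if sp.issparse(relationship):
        relationship = relationship.toarray()
    relationship = np.asarray(relationship, dtype=np.float64)
    if is_inverse:
        relationship = np.linalg.inv(relationship)
    pos = {a: i for i, a in enumerate(relationship_ids)}
    idx = np.array([pos[a] for a in animals], dtype=np.int64)
    return relationship[np.ix_(idx, idx)]


def reml_fit(
    model: ModelSpec,
    phenotypes: PhenotypeTable,
    relationship: np.ndarray | sp.spmatrix,
    relationship_ids: list[str],
    mode: str = "single",
    is_inverse: bool = False,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> REMLResult:
    """AI-REML fit of one trait (``mode='single'``) or a trait pair
    (``mode='bivariate'``, first two traits of the model)."""
    data = phenotypes.data
    if mode == "single":
        trait = model.traits[0]
        sub = data.loc[data[trait].notna()].reset_index(drop=True)
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 records for trait {trait}")
        x, _ = build_design(sub, model.factors)
        y = sub[trait].to_numpy(dtype=np.float64)
        k = _relationship_submatrix(relationship, relationship_ids, sub["animal"].tolist(), is_inverse)
        theta, cov, ll, converged, n_iter, gnorm = _fit_single(y, x, k, tol, max_iter)
        vc = VarianceComponents(
            traits=[trait],
            sigma_a=np.array([[theta[0]]]),
            sigma_e=np.array([[theta[1]]]),
            sampling_cov=cov,
        )
        h2, h2se = heritability(vc)
        return REMLResult(
            vc=vc,
            h2={trait: h2},
            h2_se={trait: h2se},
            r_g=None,
            r_g_se=None,
            r_p=None,
            loglik=ll,
            converged=converged,
            n_iterations=n_iter,
            gradient_norm=gnorm,
        )
    if mode == "bivariate":
        t1, t2 = model.traits[:2]
        sub = data.loc[data[t1].notna() & data[t2].notna()].reset_index(drop=True)
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete records for pair ({t1}, {t2})")
        x, _ = build_design(sub, model.factors)
        y = sub[[t1, t2]].to_numpy(dtype=np.float64)
        k = _relationship_submatrix(relationship, relationship_ids, sub["animal"].tolist(), is_inverse)
        theta, cov, ll, converged, n_iter, gnorm = _fit_bivariate(y, x, k, tol, max_iter)
        sa, se = _unpack(theta)
        vc = VarianceComponents(traits=[t1, t2], sigma_a=sa, sigma_e=se, sampling_cov=cov)
        h2_1, se_1 = heritability(vc, 0)
        h2_2, se_2 = heritability(vc, 1)
        rg, rg_se = genetic_correlation(vc)
        sp_tot = sa + se
        rp = float(sp_tot[0, 1] / np.sqrt(sp_tot[0, 0] * sp_tot[1, 1]))
        return REMLResult(
            vc=vc,
            h2={t1: h2_1, t2: h2_2},
            h2_se={t1: se_1, t2: se_2},
            r_g=rg,
            r_g_se=rg_se,
            r_p=rp,
            loglik=ll,
            converged=converged,
            n_iterations=n_iter,
            gradient_norm=gnorm,
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# derived parameters with delta-method SEs
# ---------------------------------------------------------------------------


def heritability(vc: VarianceComponents, trait_index: int = 0) -> tuple[float, float]:
    """h2 = sigma2_a / (sigma2_a + sigma2_e), delta-method SE (nan when no
    sampling covariance is available)."""
    sa = float(vc.sigma_a[trait_index, trait_index])
    se_ = float(vc.sigma_e[trait_index, trait_index])
    tot = sa + se_
    if tot <= 0:
        raise ValueError("total variance must be positive")
    h2 = sa / tot
    if vc.sampling_cov is None or not np.all(np.isfinite(vc.sampling_cov)):
        return h2, float("nan")
    grad = np.zeros(len(vc.param_names))
    if len(vc.traits) == 1:
        ia, ie = 0, 1
    else:
        ia = 0 if trait_index == 0 else 2
        ie = 3 if trait_index == 0 else 5
    grad[ia] = se_ / tot**2
    grad[ie] = -sa / tot**2
    var = float(grad @ vc.sampling_cov @ grad)
    return h2, float(np.sqrt(max(var, 0.0)))


def genetic_correlation(vc: VarianceComponents) -> tuple[float, float]:
    """r_g = cov_a / sqrt(sigma2_a1 sigma2_a2) with delta-method SE."""
    if len(vc.traits) < 2:
        raise ValueError("genetic correlation requires a bivariate fit")
    a11, a12, a22 = vc.sigma_a[0, 0], vc.sigma_a[0, 1], vc.sigma_a[1, 1]
    if a11 <= 0 or a22 <= 0:
        raise ValueError("both additive variances must be positive")
    rg = a12 / np.sqrt(a11 * a22)
    if vc.sampling_cov is None or not np.all(np.isfinite(vc.sampling_cov)):
        return float(rg), float("nan")
    grad = np.zeros(6)
    grad[0] = -0.5 * a12 / (a11 ** 1.5 * np.sqrt(a22))
    grad[1] = 1.0 / np.sqrt(a11 * a22)
    grad[2] = -0.5 * a12 / (a22 ** 1.5 * np.sqrt(a11))
    var = float(grad @ vc.sampling_cov @ grad)
    return float(rg), float(np.sqrt(max(var, 0.0)))
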