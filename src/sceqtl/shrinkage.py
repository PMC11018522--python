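"""Multivariate empirical-Bayes shrinkage of effects across cell types.

Effects estimated independently per cell type (condition) are modeled
jointly: the true effect vector b_t of test t follows a mixture of
zero-centered multivariate normals,

    b_t ~ pi_0 delta_0 + sum_k pi_k N(0, omega_k U_k),

with a library of canonical covariances (identity, per-condition
singletons, equal effects) and data-driven covariances learned from the
strongest signals (top principal components and their extreme-deconvolution
refinement).  Observations are b_hat_t ~ N(b_t, S_t V S_t) with S_t the
per-condition standard errors and V a residual correlation estimated from
null-like tests.  Mixture weights are fitted by maximum likelihood (EM) on a
random subset of tests; posteriors give shrunken per-condition effects and
the local false sign rate (LFSR): the posterior probability that the
reported sign is wrong or the effect is null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BIG_SE = 1e6  # standard error assigned to conditions where a test is missing


@dataclass
class EffectPanel:
    """tests x conditions effect estimates and standard errors."""

    bhat: np.ndarray
    shat: np.ndarray
    ids: pd.DataFrame  # columns gene, snp
    conditions: list[str]

    def __post_init__(self) -> None:
        self.bhat = np.asarray(self.bhat, dtype=float)
        self.shat = np.asarray(self.shat, dtype=float)
        if self.bhat.shape != self.shat.shape:
            raise ValueError("bhat and shat shapes differ")
        if (self.shat <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def n_tests(self) -> int:
        return self.bhat.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.bhat.shape[1]

    def z(self) -> np.ndarray:
        return self.bhat / self.shat

    def observed(self) -> np.ndarray:
        """Mask of entries actually measured (not missing-filled)."""
        return self.shat < _BIG_SE / 2


@dataclass
class MashFit:
    """Fitted mixture prior and the inputs needed for posteriors."""

    u_names: list[str]
    u_list: list[np.ndarray]
    omega_grid: np.ndarray
    components: list[tuple[int, float]]  # (U index, omega); index -1 encodes the null
    pi: np.ndarray
    v: np.ndarray
    loglik: float
    conditions: list[str] = field(default_factory=list)
    loglik_matrix: np.ndarray | None = None  # tests x components, set when the
    # mixture was fitted on the full panel (reused by the posterior pass)


def panel_from_assoc(
    table: pd.DataFrame,
    beta_col: str = "beta",
    se_col: str = "se",
    dof_col: str | None = "dof",
) -> EffectPanel:
    """Pivot a long association table into a tests x cell-types panel.

    Tests missing in a cell type (e.g. SNPs filtered there) get b_hat = 0
    with an enormous standard error, which makes them uninformative for that
    condition without dropping the test.

    When the table carries a ``dof`` column, standard errors are inflated to
    normal-equivalent ones: the Wald statistic b/s follows a t distribution
    with the residual degrees of freedom, and the multivariate shrinkage
    model assumes normal noise, so s is replaced by |b| / Phi^-1(p_t/2)
    (identity in the bulk, heavier in the tails).
    """
    b = table.pivot_table(index=["gene", "snp"], columns="cell_type", values=beta_col)
    s = table.pivot_table(index=["gene", "snp"], columns="cell_type", values=se_col)
    conditions = list(b.columns)
    ids = b.index.to_frame(index=False)
    bhat = b.to_numpy(dtype=float)
    shat = s.to_numpy(dtype=float)
    if dof_col is not None and dof_col in table.columns:
        d = table.pivot_table(index=["gene", "snp"], columns="cell_type", values=dof_col)
        dof = d.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat = np.abs(bhat / shat)
            p_t = 2.0 * stats.t.sf(t_stat, np.maximum(dof, 1.0))
            z_eq = stats.norm.isf(p_t / 2.0)
            good = np.isfinite(z_eq) & (z_eq > 1e-8) & np.isfinite(bhat)
            shat = np.where(good, np.abs(bhat) / np.where(good, z_eq, 1.0), shat)
    missing = ~np.isfinite(bhat) | ~np.isfinite(shat)
    bhat[missing] = 0.0
    shat[missing] = _BIG_SE
    return EffectPanel(bhat=bhat, shat=shat, ids=ids, conditions=conditions)


# ---------------------------------------------------------------------------
# mixture likelihood machinery


def _component_covs(
    shat: np.ndarray, v: np.ndarray, u: np.ndarray | None, omega: float
) -> np.ndarray:
    """Batched per-test marginal covariance omega*U + S_t V S_t."""
    svs = shat[:, :, None] * v[None] * shat[:, None, :]
    if u is None:
        return svs
    return omega * u[None] + svs


def _mvn_logpdf_batch(b: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(b_t; 0, cov_t) for stacked tests."""
    r = b.shape[1]
    chol = np.linalg.cholesky(cov)
    logdet = 2.0 * np.log(np.einsum("tii->ti", chol)).sum(axis=1)
    sol = np.linalg.solve(cov, b[:, :, None])[:, :, 0]
    quad = np.einsum("ti,ti->t", b, sol)
    return -0.5 * (r * np.log(2 * np.pi) + logdet + quad)


def _loglik_matrix(panel: EffectPanel, fit_components, u_list, v) -> np.ndarray:
    """tests x components log marginal likelihood matrix."""
    cols = []
    for ui, omega in fit_components:
        u = None if ui < 0 else u_list[ui]
        cov = _component_covs(panel.shat, v, u, omega)
        cols.append(_mvn_logpdf_batch(panel.bhat, cov))
    return np.column_stack(cols)


def default_omega_grid(panel: EffectPanel) -> np.ndarray:
    """Geometric scaling grid from (min s)^2 / 10 to 4 max(b^2), sqrt(2)-spaced."""
    obs = panel.observed()
    smin = panel.shat[obs].min()
    bmax = np.abs(panel.bhat[obs]).max()
    lo = smin**2 / 10.0
    hi = max(4.0 * bmax**2, lo * 2.0)
    n = int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0)))) + 1
    return lo * np.sqrt(2.0) ** np.arange(n)


def _em_weights(loglik: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> tuple[np.ndarray, float]:
    """EM for mixture weights given a fixed log-likelihood matrix."""
    t, k = loglik.shape
    pi = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        logw = loglik + np.log(np.maximum(pi, 1e-300))
        m = logw.max(axis=1, keepdims=True)
        w = np.exp(logw - m)
        tot = w.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        gamma = w / tot
        pi = gamma.mean(axis=0)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            prev = ll
            break
        prev = ll
    return pi, prev


# ---------------------------------------------------------------------------
# univariate adaptive shrinkage (used by select_strong)


def univariate_lfsr(bhat: np.ndarray, shat: np.ndarray) -> np.ndarray:
    """Adaptive-shrinkage LFSR for one condition.

    Normal-mixture prior (point mass at zero plus zero-centered normals on a
    geometric variance grid) fitted by EM; returns the per-test LFSR.
    """
    panel = EffectPanel(
        bhat=np.asarray(bhat, float)[:, None],
        shat=np.asarray(shat, float)[:, None],
        ids=pd.DataFrame({"gene": np.arange(len(bhat)), "snp": 0}),
        conditions=["x"],
    )
    grid = default_omega_grid(panel)
    one = np.ones((1, 1))
    comps = [(-1, 0.0)] + [(0, float(w)) for w in grid]
    ll = _loglik_matrix(panel, comps, [one], np.ones((1, 1)))
    pi, _ = _em_weights(ll)
    fit = MashFit(
        u_names=["one"], u_list=[one], omega_grid=grid, components=comps,
        pi=pi, v=np.ones((1, 1)), loglik=0.0, conditions=["x"],
    )
    _, _, lfsr = posterior(panel, fit)
    return lfsr[:, 0]


def select_strong(panel: EffectPanel, lfsr_threshold: float = 0.1) -> np.ndarray:
    """Indices of tests with univariate LFSR below threshold in any condition."""
    obs = panel.observed()
    minl = np.ones(panel.n_tests)
    for r in range(panel.n_conditions):
        mask = obs[:, r]
        if mask.sum() < 3:
            continue
        l = univariate_lfsr(panel.bhat[mask, r], panel.shat[mask, r])
        col = np.ones(panel.n_tests)
        col[mask] = l
        minl = np.minimum(minl, col)
    idx = np.flatnonzero(minl < lfsr_threshold)
    if idx.size == 0:
        raise ValueError(
            "no strong associations at LFSR < "
            f"{lfsr_threshold}; raise the threshold or check the input panel"
        )
    logger.info("select_strong: %d of %d tests", idx.size, panel.n_tests)
    return idx


# ---------------------------------------------------------------------------
# covariance library


def _psd_clip(u: np.ndarray, rel_floor: float = 1e-10) -> np.ndarray:
    u = (u + u.T) / 2.0
    w, vv = np.linalg.eigh(u)
    top = max(w.max(), 0.0)
    if top == 0:
        return np.zeros_like(u)
    w = np.clip(w, rel_floor * top, None)
    return (vv * w) @ vv.T


def canonical_covariances(r: int) -> dict[str, np.ndarray]:
    """Identity, per-condition singletons, and the equal-effects matrix."""
    if r == 1:
        return {"equal": np.ones((1, 1))}
    out = {"identity": np.eye(r), "equal": np.ones((r, r))}
    for j in range(r):
        u = np.zeros((r, r))
        u[j, j] = 1.0
        out[f"singleton_{j}"] = u
    return out


def _ed_refine(
    bhat: np.ndarray,
    shat: np.ndarray,
    v: np.ndarray,
    u_init: list[np.ndarray],
    n_iter: int = 50,
) -> list[np.ndarray]:
    """Extreme-deconvolution EM: refine candidate prior covariances.

    Fits sum_j pi_j N(0, U_j + S_t V S_t) to the strong effects, updating
    each U_j from the responsibility-weighted posterior second moments.
    """
    k = len(u_init)
    us = [u.copy() for u in u_init]
    pi = np.full(k, 1.0 / k)
    svs = shat[:, :, None] * v[None] * shat[:, None, :]
    for _ in range(n_iter):
        logl = np.column_stack(
            [_mvn_logpdf_batch(bhat, u[None] + svs) for u in us]
        ) + np.log(np.maximum(pi, 1e-300))
        m = logl.max(axis=1, keepdims=True)
        w = np.exp(logl - m)
        gamma = w / w.sum(axis=1, keepdims=True)
        for j in range(k):
            cov = us[j][None] + svs
            # posterior of b given component j: mean m_t, cov C_t
            gain = np.linalg.solve(cov, np.broadcast_to(us[j], cov.shape))
            mean = np.einsum("tij,ti->tj", gain.transpose(0, 2, 1), bhat)
            c = us[j] - us[j] @ gain  # note: gain = cov^-1 U, so U - U cov^-1 U
            second = c + np.einsum("ti,tj->tij", mean, mean)
            wgt = gamma[:, j]
            tot = wgt.sum()
            if tot < 1e-12:
                continue
            us[j] = _psd_clip(np.einsum("t,tij->ij", wgt, second) / tot)
        pi = gamma.mean(axis=0)
    return us


def build_covariances(
    strong_bhat: np.ndarray,
    strong_shat: np.ndarray | None = None,
    v: np.ndarray | None = None,
    n_pcs: int = 5,
    ed_iters: int = 50,
) -> dict[str, np.ndarray]:
    """Canonical plus data-driven covariance library.

    Data-driven matrices: rank-1 outer products of the top ``n_pcs``
    principal components of the strong-effect matrix, the rank-``n_pcs``
    PCA reconstruction, and its extreme-deconvolution refinement.
    """
    b = np.asarray(strong_bhat, dtype=float)
    n, r = b.shape
    out = canonical_covariances(r)
    if r == 1:
        return out
    if n == 0 or not np.isfinite(b).all() or np.allclose(b, 0):
        logger.warning("build_covariances: degenerate strong set, canonical only")
        return out
    n_pcs = min(n_pcs, r, n)
    _, d, vt = np.linalg.svd(b, full_matrices=False)
    for k in range(n_pcs):
        out[f"pca_{k + 1}"] = _psd_clip(d[k] ** 2 * np.outer(vt[k], vt[k]) / n)
    recon = (vt[:n_pcs].T * (d[:n_pcs] ** 2)) @ vt[:n_pcs] / n
    out["pca_rank"] = _psd_clip(recon)
    if ed_iters > 0 and strong_shat is not None:
        vv = v if v is not None else np.eye(r)
        init = [out[f"pca_{k + 1}"] for k in range(n_pcs)] + [out["pca_rank"]]
        refined = _ed_refine(b, np.asarray(strong_shat, float), vv, init, n_iter=ed_iters)
        for k in range(n_pcs):
            out[f"ed_{k + 1}"] = refined[k]
        out["ed_rank"] = refined[-1]
    return out


def estimate_null_correlation(panel: EffectPanel, z_max: float = 2.0) -> np.ndarray:
    """Residual correlation V from tests that look null in every condition."""
    z = panel.z()
    mask = (np.abs(z) < z_max).all(axis=1)
    r = panel.n_conditions
    if mask.sum() < r + 1:
        logger.warning("estimate_null_correlation: too few null-like tests, V = I")
        return np.eye(r)
    v = np.corrcoef(z[mask], rowvar=False)
    v = _psd_clip(np.atleast_2d(v))
    dd = np.sqrt(np.diag(v))
    v = v / np.outer(dd, dd)
    np.fill_diagonal(v, 1.0)
    return v


# ---------------------------------------------------------------------------
# fitting and posteriors


def fit_mixture(
    panel: EffectPanel,
    u_lib: dict[str, np.ndarray],
    omega_grid: np.ndarray | None = None,
    v: np.ndarray | None = None,
    subset_size: int = 10_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MashFit:
    """Fit mixture weights by EM on a random subset of tests.

    The component library is the null (point mass at zero) plus every
    (U, omega) pair; the fitted weights are then reused for posteriors on
    the full panel.
    """
    r = panel.n_conditions
    v = v if v is not None else np.eye(r)
    omega_grid = omega_grid if omega_grid is not None else default_omega_grid(panel)
    rng = np.random.default_rng(seed)
    if panel.n_tests > subset_size:
        idx = rng.choice(panel.n_tests, size=subset_size, replace=False)
        sub = EffectPanel(
            bhat=panel.bhat[idx], shat=panel.shat[idx],
            ids=panel.ids.iloc[idx].reset_index(drop=True), conditions=panel.conditions,
        )
    else:
        sub = panel
    u_names = list(u_lib)
    u_list = [u_lib[k] for k in u_names]
    comps: list[tuple[int, float]] = [(-1, 0.0)]
    for ui in range(len(u_list)):
        for w in omega_grid:
            comps.append((ui, float(w)))
    ll = _loglik_matrix(sub, comps, u_list, v)
    if not np.isfinite(ll).all():
        bad = int(np.argwhere(~np.isfinite(ll))[0][0])
        raise FloatingPointError(f"non-finite likelihood at test index {bad}")
    pi, loglik = _em_weights(ll, tol=tol, max_iter=max_iter)
    return MashFit(
        u_names=u_names, u_list=u_list, omega_grid=np.asarray(omega_grid),
        components=comps, pi=pi, v=v, loglik=loglik, conditions=list(panel.conditions),
        loglik_matrix=ll if sub is panel else None,
    )


def posterior(
    panel: EffectPanel,
    fit: MashFit,
    pi_floor: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior means, SDs, and LFSR for every test and condition.

    Per mixture component k the posterior of b_t is normal with
    mean = omega U (omega U + S V S)^-1 b_hat and covariance
    omega U - omega U (omega U + S V S)^-1 omega U; the overall posterior is
    the responsibility-weighted mixture.  LFSR_r = min(P(b_r >= 0),
    P(b_r <= 0)), each side including the point mass at zero contributed by
    the null and by components with no variance in condition r.
    """
    t, r = panel.bhat.shape
    keep = [i for i, p in enumerate(fit.pi) if p > pi_floor]
    if fit.loglik_matrix is not None and fit.loglik_matrix.shape[0] == t:
        logl = fit.loglik_matrix[:, keep]
    else:
        logl = _loglik_matrix(panel, [fit.components[i] for i in keep],
                              fit.u_list, fit.v)
    logw = logl + np.log(np.asarray([fit.pi[i] for i in keep]))
    m = logw.max(axis=1, keepdims=True)
    gamma = np.exp(logw - m)
    gamma /= gamma.sum(axis=1, keepdims=True)

    post_mean = np.zeros((t, r))
    post_m2 = np.zeros((t, r))
    p_neg = np.zeros((t, r))
    p_pos = np.zeros((t, r))
    p_zero = np.zeros((t, r))
    for gi, ci in enumerate(keep):
        ui, omega = fit.components[ci]
        g = gamma[:, gi][:, None]
        if ui < 0:
            p_zero += g
            continue
        u = omega * fit.u_list[ui]
        cov = _component_covs(panel.shat, fit.v, fit.u_list[ui], omega)
        gain = np.linalg.solve(cov, np.broadcast_to(u, cov.shape))  # cov^-1 U'
        mean = np.einsum("tij,ti->tj", gain.transpose(0, 2, 1), panel.bhat)
        cvar = np.maximum(np.diag(u)[None, :] - np.einsum("ij,tjk->tik", u, gain).diagonal(axis1=1, axis2=2), 0.0)
        sd = np.sqrt(cvar)
        post_mean += g * mean
        post_m2 += g * (cvar + mean**2)
        zero = sd <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            zneg = np.where(zero, 0.0, stats.norm.cdf(0.0, loc=mean, scale=np.where(zero, 1.0, sd)))
        p_neg += g * zneg
        p_pos += g * np.where(zero, 0.0, 1.0 - zneg)
        p_zero += g * zero
    post_var = np.maximum(post_m2 - post_mean**2, 0.0)
    post_sd = np.sqrt(post_var)
    lfsr = np.minimum(p_neg + p_zero, p_pos + p_zero)
    return post_mean, post_sd, np.clip(lfsr, 0.0, 1.0)


def mash_pipeline(
    panel: EffectPanel,
    n_pcs: int = 5,
    ed_iters: int = 50,
    strong_lfsr: float = 0.1,
    subset_size: int = 10_000,
    seed: int = 0,
) -> tuple[MashFit, np.ndarray, np.ndarray, np.ndarray]:
    """Strong-set selection -> covariance library -> EM fit -> posteriors."""
    v = estimate_null_correlation(panel)
    try:
        strong = select_strong(panel, lfsr_threshold=strong_lfsr)
    except ValueError:
        # nothing to learn data-driven covariances from; fitting them to noise
        # extremes overfits the null, so fall back to the canonical library
        logger.warning("mash_pipeline: no strong tests; canonical covariances only")
        strong = None
    if strong is None:
        u_lib = canonical_covariances(panel.n_conditions)
    else:
        u_lib = build_covariances(
            panel.bhat[strong], panel.shat[strong], v=v, n_pcs=n_pcs, ed_iters=ed_iters
        )
    fit = fit_mixture(panel, u_lib, v=v, subset_size=subset_size, seed=seed)
    mean, sd, lfsr = posterior(panel, fit)
    return fit, mean, sd, lfsr
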