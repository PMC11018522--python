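"""Mixed-model cis-eQTL association and disease-interaction testing.

Per cell type, each gene's pseudobulk vector is quantile-normalized to a
standard normal, expression principal components are regressed out (eQTL
mapping) or included as fixed effects (interaction mapping), and a linear
mixed model with two random effects is fitted per gene:

    y = C alpha + u_g + u_w + e
    Cov(y) = sigma2_g * K + sigma2_w * diag(w) + sigma2_e * I

where K is the genomic relationship matrix (population structure /
relatedness) and w = 1/nCells captures the extra pseudobulk noise of donors
with few aggregated cells.  Variance components are estimated once per gene
by restricted maximum likelihood on the null model (no SNP); every cis SNP
is then tested by generalized least squares under the fitted covariance
(Wald test, two-sided t p-value on the residual degrees of freedom).  The
interaction model adds disease status and a genotype x status term and
tests the interaction coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genotypes import GenotypeMatrix, KinshipMatrix
from .qc import PseudobulkTensor

logger = logging.getLogger(__name__)


@dataclass
class AssocModelSpec:
    """Model settings for cis-eQTL mapping."""

    n_expr_pcs: int = 20
    quantile_normalize: bool = True
    use_kinship: bool = True
    use_ncell_weights: bool = True
    min_donors: int = 40


@dataclass
class NullModel:
    """Fitted null-model variance components and whitening transform."""

    sigma2_g: float
    sigma2_w: float
    sigma2_e: float
    whitening: np.ndarray  # T with Cov(T y) ~= I under the fitted model
    reml: float


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5)/n).

    Ties get the average rank.  Raises on constant input (no ranking
    possible).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.nanstd(y) == 0:
        raise ValueError("cannot quantile-normalize a constant vector")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


def regress_out_pcs(expr: np.ndarray, n_pcs: int = 20) -> np.ndarray:
    """Residualize a donor x gene matrix on its own top principal components.

    The matrix is column-centered; donor-space PCs are the left singular
    vectors of the centered matrix; each gene is replaced by its residual
    after projecting out PCs 1..n_pcs (the intercept is absorbed by
    centering).  ``n_pcs=0`` returns the centered matrix.
    """
    expr = np.asarray(expr, dtype=float)
    n, _ = expr.shape
    if n_pcs >= n:
        raise ValueError(f"n_pcs={n_pcs} must be < n_donors={n}")
    xc = expr - expr.mean(axis=0)
    if n_pcs == 0:
        return xc
    u, _, _ = np.linalg.svd(xc, full_matrices=False)
    p = u[:, :n_pcs]
    return xc - p @ (p.T @ xc)


def _reml_neg_loglik(
    y: np.ndarray, c: np.ndarray, k: np.ndarray, w: np.ndarray, gam_g: float, gam_w: float
) -> tuple[float, float]:
    """Negative restricted log-likelihood profiled over sigma2_e.

    V = gam_g K + gam_w diag(w) + I; returns (-2 reml, sigma2_e_hat).
    """
    n, p = c.shape
    v = gam_g * k + np.diag(gam_w * w) + np.eye(n)
    try:
        cf = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, np.nan
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    vic = linalg.cho_solve(cf, c, check_finite=False)
    ctvc = c.T @ vic
    try:
        alpha = np.linalg.solve(ctvc, vic.T @ y)
    except np.linalg.LinAlgError:
        return np.inf, np.nan
    r = y - c @ alpha
    quad = float(r @ linalg.cho_solve(cf, r, check_finite=False))
    sigma2 = quad / (n - p)
    sign, logdet_cc = np.linalg.slogdet(ctvc)
    if sign <= 0 or sigma2 <= 0:
        return np.inf, np.nan
    neg2 = logdet_v + logdet_cc + (n - p) * np.log(sigma2)
    return neg2, sigma2


def fit_null_lmm(
    y: np.ndarray,
    covariates: np.ndarray,
    kinship: KinshipMatrix | np.ndarray | None,
    weights: np.ndarray | None,
    grid: tuple[float, ...] = (0.0, 1e-2, 1e-1, 0.3, 1.0, 3.0, 10.0),
) -> NullModel:
    """REML fit of the two-random-effect null model; returns a whitener.

    The two variance ratios (sigma2_g, sigma2_w)/sigma2_e are profiled over
    a coarse log grid and refined by Nelder-Mead; sigma2_e is profiled out
    analytically.  The whitening transform is the inverse Cholesky factor of
    the fitted covariance, so Cov(T y) is the identity under the model.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    k = kinship.values if isinstance(kinship, KinshipMatrix) else kinship
    if k is None:
        k = np.zeros((n, n))
        grid_g = (0.0,)
    else:
        k = np.asarray(k, dtype=float)
        grid_g = grid
    if weights is None:
        w = np.zeros(n)
        grid_w = (0.0,)
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("random-effect weights must be positive")
        grid_w = grid

    best = (np.inf, 0.0, 0.0, np.nan)
    for gg in grid_g:
        for gw in grid_w:
            neg2, s2 = _reml_neg_loglik(y, c, k, w, gg, gw)
            if neg2 < best[0]:
                best = (neg2, gg, gw, s2)
    if not np.isfinite(best[0]):
        raise RuntimeError("REML did not find a finite starting point")

    # Nelder-Mead refinement in log-ratio space (zeros pinned to a tiny floor)
    from scipy.optimize import minimize

    x0 = np.log(np.maximum([best[1], best[2]], 1e-8))

    def objective(x: np.ndarray) -> float:
        return _reml_neg_loglik(y, c, k, w, float(np.exp(x[0])), float(np.exp(x[1])))[0]

    res = minimize(objective, x0, method="Nelder-Mead", options={"xatol": 2e-3, "fatol": 1e-5, "maxiter": 80})
    if np.isfinite(res.fun) and res.fun < best[0]:
        gg, gw = np.exp(res.x)
        neg2, s2 = _reml_neg_loglik(y, c, k, w, float(gg), float(gw))
        if neg2 <= best[0]:
            best = (neg2, float(gg), float(gw), s2)
    neg2, gam_g, gam_w, sigma2_e = best
    if not np.isfinite(sigma2_e):
        raise RuntimeError("REML fit failed to converge to a finite variance")

    cov = sigma2_e * (gam_g * k + np.diag(gam_w * w) + np.eye(n))
    try:
        l = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # clip tiny negative eigenvalues of a non-PSD kinship contribution
        logger.info("covariance not PD; clipping eigenvalues")
        ew, ev = np.linalg.eigh(cov)
        ew = np.clip(ew, 1e-10 * ew.max(), None)
        l = np.linalg.cholesky((ev * ew) @ ev.T)
    t = linalg.solve_triangular(l, np.eye(n), lower=True, check_finite=False)
    return NullModel(
        sigma2_g=sigma2_e * gam_g,
        sigma2_w=sigma2_e * gam_w,
        sigma2_e=sigma2_e,
        whitening=t,
        reml=-0.5 * neg2,
    )


def test_snp(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray,
    whitening: np.ndarray,
    test_col: int = -1,
    extra: np.ndarray | None = None,
    robust: bool = False,
) -> tuple[float, float, float]:
    """GLS Wald test of one design column under the whitened model.

    The design is [covariates, dosage] (plus ``extra`` columns, e.g. a
    genotype x disease product); ``test_col`` selects the tested
    coefficient.  Returns (beta, se, two-sided p).  The p-value uses the t
    distribution with the residual degrees of freedom: with interaction
    designs a fifth of the donors' information goes into covariates, and
    the empirical-Bayes stage downstream is sensitive to tail
    miscalibration of a plain normal approximation.

    ``robust=True`` replaces the model-based variance with an HC3 sandwich
    estimator on the whitened design.  Genotype x environment interaction
    tests are notoriously anti-conservative when the residual variance
    depends on genotype or group (the very situation a true interaction in
    the data creates for a permuted-label scan), and the sandwich variance
    restores calibration with little power cost when the model is correct.
    """
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    cols = [c, np.asarray(dosage, dtype=float)[:, None]]
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float)[:, None])
    x = np.column_stack(cols)
    if np.std(x[:, test_col]) == 0:
        raise ValueError("tested column is constant across donors")
    tx = whitening @ x
    ty = whitening @ np.asarray(y, dtype=float)
    xtx = tx.T @ tx
    xty = tx.T @ ty
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ xty
    resid = ty - tx @ coef
    dof = max(x.shape[0] - x.shape[1], 1)
    beta = float(coef[test_col])
    if robust:
        # HC2: weight squared residuals by 1/(1-h_ii); HC3 over-corrects at
        # the leverage these interaction designs reach (p/n ~ 0.4)
        h = np.einsum("ij,jk,ik->i", tx, xtx_inv, tx)
        h = np.clip(h, 0.0, 0.999)
        w2 = resid**2 / (1.0 - h)
        meat = tx.T @ (tx * w2[:, None])
        var = (xtx_inv @ meat @ xtx_inv)[test_col, test_col]
    else:
        sigma2 = float(resid @ resid) / dof
        var = sigma2 * xtx_inv[test_col, test_col]
    if not np.isfinite(var) or var <= 0:
        raise ValueError("degenerate design: tested coefficient has no variance")
    se = float(np.sqrt(var))
    t_stat = beta / se
    p = 2.0 * stats.t.sf(abs(t_stat), dof)
    return beta, se, max(p, np.finfo(float).tiny)


def _gls_wald_all(
    y: np.ndarray, x: np.ndarray, whitening: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One whitened least-squares fit; Wald (beta, se, t-based p) per column."""
    tx = whitening @ x
    ty = whitening @ y
    xtx = tx.T @ tx
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ (tx.T @ ty)
    resid = ty - tx @ coef
    dof = max(x.shape[0] - x.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    var = sigma2 * np.diag(xtx_inv)
    if not np.isfinite(var).all() or (var <= 0).any():
        raise ValueError("degenerate design: a coefficient has no variance")
    se = np.sqrt(var)
    p = np.maximum(2.0 * stats.t.sf(np.abs(coef / se), dof), np.finfo(float).tiny)
    return coef, se, p


def _observed_maf(dosage: np.ndarray) -> float:
    p = float(np.nanmean(dosage) / 2.0)
    return min(p, 1.0 - p)


def _prepare_celltype(
    pb: PseudobulkTensor,
    celltype: str,
    g: GenotypeMatrix,
    kinship: KinshipMatrix | None,
    spec: AssocModelSpec,
    residualize_pcs: bool,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Align donors, INT-transform, and optionally residualize PCs.

    Returns (expr_df_transformed, dosage_rows, K_sub, weights, pcs).
    """
    expr = pb.expr[celltype]
    donors = [d for d in expr.index if d in set(g.donors)]
    expr = expr.loc[donors]
    didx = [g.donors.index(d) for d in donors]
    dose = g.imputed()[didx, :]
    mat = expr.to_numpy(dtype=float)
    if spec.quantile_normalize:
        cols = []
        for j in range(mat.shape[1]):
            col = mat[:, j]
            if np.std(col) == 0:
                cols.append(np.zeros_like(col))
            else:
                cols.append(inverse_normal_transform(col))
        mat = np.column_stack(cols)
    # cap PCs so the design keeps a usable residual dof at small donor counts
    n_pcs = min(spec.n_expr_pcs, max((len(donors) - 10) // 2, 0), mat.shape[1])
    if n_pcs > 0:
        xc = mat - mat.mean(axis=0)
        u, _, _ = np.linalg.svd(xc, full_matrices=False)
        pcs = u[:, :n_pcs]
    else:
        pcs = np.zeros((len(donors), 0))
    if residualize_pcs and n_pcs > 0:
        mat = (mat - mat.mean(axis=0)) - pcs @ (pcs.T @ (mat - mat.mean(axis=0)))
    ksub = None
    if spec.use_kinship and kinship is not None:
        kidx = [kinship.donors.index(d) for d in donors]
        ksub = kinship.values[np.ix_(kidx, kidx)]
    wsub = None
    if spec.use_ncell_weights:
        nc = pb.ncells.loc[donors, celltype].to_numpy(dtype=float)
        wsub = 1.0 / np.maximum(nc, 1.0)
    out = pd.DataFrame(mat, index=donors, columns=expr.columns)
    return out, dose, ksub, wsub, pcs


def map_cis(
    pb: PseudobulkTensor,
    g: GenotypeMatrix,
    cis,
    kinship: KinshipMatrix | None = None,
    spec: AssocModelSpec | None = None,
) -> pd.DataFrame:
    """Per-cell-type mixed-model cis-eQTL scan.

    For every retained cell type: inverse-normal transform each gene,
    regress out expression PCs, fit the null LMM once per gene, and Wald-test
    every cis SNP.  Returns the association table with columns
    (cell_type, gene, snp, beta, se, p, n, maf).
    """
    spec = spec or AssocModelSpec()
    records = []
    for ct in pb.celltypes:
        expr, dose, ksub, wsub, _ = _prepare_celltype(pb, ct, g, kinship, spec, residualize_pcs=True)
        donors = list(expr.index)
        if len(donors) < spec.min_donors:
            logger.info("map_cis: cell type %s below %d donors, skipped", ct, spec.min_donors)
            continue
        intercept = np.ones((len(donors), 1))
        for gene in expr.columns:
            if gene not in cis:
                continue
            snp_idx = cis[gene]
            if len(snp_idx) == 0:
                continue
            y = expr[gene].to_numpy()
            if np.std(y) == 0:
                logger.info("map_cis: gene %s constant in %s, skipped", gene, ct)
                continue
            null = fit_null_lmm(y, intercept, ksub, wsub)
            for j in snp_idx:
                dj = dose[:, j]
                if np.std(dj) == 0:
                    continue
                try:
                    beta, se, p = test_snp(y, dj, intercept, null.whitening)
                except ValueError:
                    logger.info("map_cis: degenerate design for %s/%s, skipped", gene, g.snp_meta["id"].iat[j])
                    continue
                records.append(
                    (ct, gene, g.snp_meta["id"].iat[j], beta, se, p, len(donors),
                     _observed_maf(dj), len(donors) - 2)
                )
    return pd.DataFrame(
        records, columns=["cell_type", "gene", "snp", "beta", "se", "p", "n", "maf", "dof"]
    )


def map_interaction(
    pb: PseudobulkTensor,
    g: GenotypeMatrix,
    cis,
    disease: pd.Series,
    kinship: KinshipMatrix | None = None,
    spec: AssocModelSpec | None = None,
    min_donors_per_group: int = 10,
    maf_per_group_min: float = 0.05,
) -> pd.DataFrame:
    """Genotype x disease interaction eQTL scan.

    Cell types need at least ``min_donors_per_group`` donors in each disease
    group; SNPs with MAF below ``maf_per_group_min`` in either group are
    removed before testing and again post hoc on the observed per-group MAF.
    Expression PCs enter as fixed effects and are NOT regressed out, because
    disease status can be strongly correlated with leading PCs.  Returns the
    association table with interaction columns (beta_int, se_int, p_int).
    """
    spec = spec or AssocModelSpec()
    records = []
    for ct in pb.celltypes:
        expr, dose, ksub, wsub, pcs = _prepare_celltype(pb, ct, g, kinship, spec, residualize_pcs=False)
        donors = list(expr.index)
        d = (disease.loc[donors] == "ILD").to_numpy(dtype=float)
        n_case, n_ctrl = int(d.sum()), int((1 - d).sum())
        if min(n_case, n_ctrl) < min_donors_per_group:
            logger.info(
                "map_interaction: cell type %s has %d ILD / %d control donors, excluded",
                ct, n_case, n_ctrl,
            )
            continue
        covar = np.column_stack([np.ones(len(donors)), pcs, d])
        for gene in expr.columns:
            if gene not in cis:
                continue
            snp_idx = cis[gene]
            if len(snp_idx) == 0:
                continue
            y = expr[gene].to_numpy()
            if np.std(y) == 0:
                continue
            null = fit_null_lmm(y, covar, ksub, wsub)
            for j in snp_idx:
                dj = dose[:, j]
                maf_case = _observed_maf(dj[d == 1])
                maf_ctrl = _observed_maf(dj[d == 0])
                if min(maf_case, maf_ctrl) <= maf_per_group_min:
                    continue
                inter = dj * d
                if np.std(inter) == 0 or np.std(dj) == 0:
                    continue
                # one fit: main genotype coefficient is second-to-last,
                # the interaction coefficient is last
                try:
                    coefs, ses, ps = _gls_wald_all(
                        y, np.column_stack([covar, dj, inter]), null.whitening
                    )
                except ValueError:
                    logger.info("map_interaction: degenerate design for %s/%s, skipped", gene, g.snp_meta["id"].iat[j])
                    continue
                bi, si, pi = float(coefs[-1]), float(ses[-1]), float(ps[-1])
                bg, sg, pg = float(coefs[-2]), float(ses[-2]), float(ps[-2])
                records.append(
                    (
                        ct, gene, g.snp_meta["id"].iat[j],
                        bg, sg, pg, len(donors), _observed_maf(dj),
                        bi, si, pi, maf_case, maf_ctrl,
                        len(donors) - covar.shape[1] - 2,
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "cell_type", "gene", "snp", "beta", "se", "p", "n", "maf",
            "beta_int", "se_int", "p_int", "maf_ild", "maf_control", "dof",
        ],
    )


def permute_disease(donor_meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Donor-level permutation of disease labels (everything else fixed)."""
    rng = np.random.default_rng(seed)
    out = donor_meta.copy()
    out["disease_status"] = rng.permutation(out["disease_status"].to_numpy())
    return out


def permute_genotypes(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Donor-level permutation of genotype rows (breaks genotype-expression
    links while preserving LD and allele frequencies)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(g.n_donors)
    return GenotypeMatrix(dosage=g.dosage[perm], donors=list(g.donors), snp_meta=g.snp_meta)
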