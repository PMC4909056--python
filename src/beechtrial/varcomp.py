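"""Variance partitioning of provenance-trial traits via mixed models.

The trial design is a randomized block layout: every provenance is planted in
every block, and a trait observation decomposes additively as

    Y_ijk = μ + P_i + b_j + ε_ijk                                  (random model)

with crossed random intercepts P_i ~ N(0, σ²_inter) for provenance and
b_j ~ N(0, σ²_block) for block, and residual ε ~ N(0, σ²_intra).  Genetic
differentiation between provenances is tested with a likelihood-ratio test of
σ²_inter = 0 under REML; because the null pins a variance to the boundary of
its parameter space, the χ²₁ p-value is halved (the LR null distribution is a
50:50 mixture of χ²₀ and χ²₁).

The climate model adds the forest aridity index of each provenance's origin
as a fixed covariate,

    Y_ijk = α + β·FAI_i + P_i + b_j + ε_ijk

and tests β via an ML likelihood-ratio test (fixed effects cannot be compared
under REML).

Likelihoods are exact Gaussian (restricted) log-likelihoods evaluated through
the Woodbury identity on the low-rank covariance
V = σ²_intra·I + σ²_inter·Z_P Z_Pᵀ + σ²_block·Z_B Z_Bᵀ, so the cost per
evaluation is linear in the number of trees.  Estimation maximizes over each
boundary face (every subset of {σ²_inter, σ²_block} pinned to zero) on the
log-variance scale and keeps the best face, which handles the frequent
zero-variance estimates cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RandomModelFit",
    "VarCompSummary",
    "ClimateModelFit",
    "reml_loglik",
    "fit_random_model",
    "lrt_provenance",
    "cv_components",
    "variance_component_percents",
    "fit_climate_model",
    "LOG_TRANSFORM_TRAITS",
]

#: Traits fitted on the natural-log scale in the climate model (right-skewed
#: conductivity-per-leaf-area quantities and the Huber value).
LOG_TRANSFORM_TRAITS = frozenset({"KLemp", "KLtheo", "huber"})


# ---------------------------------------------------------------------------
# likelihood machinery


def _indicator(labels) -> np.ndarray:
    codes, uniques = pd.factorize(np.asarray(labels))
    if (codes < 0).any():
        raise ValueError("missing factor labels")
    Z = np.zeros((len(codes), len(uniques)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _gaussian_loglik(y, X, Z_blocks, variances, sigma2_e, method):
    """Exact (restricted) log-likelihood of y ~ N(Xβ, V) profiled over β.

    V = sigma2_e·I + Σ variances[k]·Z_k Z_kᵀ, via Woodbury on the stacked
    scaled design W = [√v_k·Z_k].  Returns (loglik, beta_gls, cov_beta).
    """
    n, p = X.shape
    if sigma2_e <= 0:
        raise ValueError("residual variance must be positive")
    cols = [np.sqrt(v) * Z for v, Z in zip(variances, Z_blocks) if v > 0]
    if cols:
        W = np.hstack(cols)
        A = W.T @ W
        C = sigma2_e * np.eye(A.shape[0]) + A
        Lc = np.linalg.cholesky(C)
        logdet_v = n * np.log(sigma2_e) + 2.0 * np.sum(
            np.log(np.diag(Lc))
        ) - A.shape[0] * np.log(sigma2_e)

        def vinv(M):
            WtM = W.T @ M
            return (M - W @ np.linalg.solve(C, WtM)) / sigma2_e

    else:
        logdet_v = n * np.log(sigma2_e)

        def vinv(M):
            return M / sigma2_e

    ViX = vinv(X)
    XtViX = X.T @ ViX
    XtViy = ViX.T @ y
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    quad = float(r @ vinv(r))
    cov_beta = np.linalg.inv(XtViX)

    if method == "REML":
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V⁻¹X not positive definite")
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_xvx + quad)
    elif method == "ML":
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
    else:
        raise ValueError(f"method must be 'REML' or 'ML', got {method!r}")
    return float(ll), beta, cov_beta


def reml_loglik(variances, y, provenance, block, method="REML") -> float:
    """Log-likelihood of the random model at fixed (σ²_inter, σ²_block, σ²_intra).

    ``variances`` is the triple (σ²_inter, σ²_block, σ²_intra); the first two
    may be zero (their component drops out), the residual must be positive.
    """
    s2_p, s2_b, s2_e = (float(v) for v in variances)
    if min(s2_p, s2_b, s2_e) < 0:
        raise ValueError("variances must be non-negative")
    if s2_e == 0:
        raise ValueError("residual variance must be positive (V singular)")
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    Z_blocks = [_indicator(provenance), _indicator(block)]
    ll, _, _ = _gaussian_loglik(y, X, Z_blocks, (s2_p, s2_b), s2_e, method)
    return ll


# ---------------------------------------------------------------------------
# model fits


@dataclass
class RandomModelFit:
    """Fitted random model: variance components and (restricted) likelihood."""

    mu: float
    sigma2_inter: float
    sigma2_block: float
    sigma2_intra: float
    loglik: float
    method: str
    converged: bool
    components: tuple[str, ...] = ("provenance", "block")


@dataclass
class VarCompSummary:
    """Per-trait variance decomposition (the machine twin of a results row)."""

    trait: str
    n: int
    cv_inter: float
    cv_intra: float
    vc_inter: float
    vc_block: float
    vc_intra: float
    lr: float
    delta_aic: float
    p_corrected: float


@dataclass
class ClimateModelFit:
    """ML fit of the climate (FAI) model with its likelihood-ratio test."""

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    sd_prov: float
    sd_block: float
    sd_resid: float
    loglik: float
    lr: float
    delta_aic: float
    p: float
    n: int
    converged: bool
    log_transformed: bool = False


def _moment_starts(y, Z_blocks):
    """Crude variance starts for the optimizer from group-mean spreads."""
    s2 = float(np.var(y, ddof=1)) if len(y) > 1 else 1.0
    s2 = max(s2, 1e-12)
    starts = []
    for Z in Z_blocks:
        counts = Z.sum(axis=0)
        means = (Z.T @ y) / np.maximum(counts, 1)
        v = float(np.var(means, ddof=1)) if len(means) > 1 else 0.0
        starts.append(max(v, 1e-3 * s2))
    starts.append(max(0.5 * s2, 1e-12))
    return starts


def _maximize_face(y, X, Z_blocks, free, method, starts):
    """Maximize the likelihood over one boundary face.

    ``free`` flags which of the K random components are free (the rest pinned
    to 0); the residual variance is always free.  Optimization runs on log
    variances with Nelder–Mead, which is robust for the 1–3 dimensional,
    possibly ridge-shaped REML surfaces here.
    """
    k_free = [k for k, f in enumerate(free) if f]
    y_scale = float(np.var(y)) or 1.0
    # keep V invertible and well-conditioned for degenerate (noise-free or
    # perfectly collinear) data without touching any realistic estimate
    s2e_floor = 1e-10 * y_scale
    v_cap = 1e6 * y_scale

    def unpack(theta):
        v = [0.0] * len(Z_blocks)
        for i, k in enumerate(k_free):
            v[k] = min(np.exp(theta[i]), v_cap)
        return v, max(np.exp(theta[-1]), s2e_floor)

    def nll(theta):
        if np.any(np.abs(theta) > 46):  # e^46 ~ 1e20: off the data scale
            return 1e12
        v, s2e = unpack(theta)
        try:
            ll, _, _ = _gaussian_loglik(y, X, Z_blocks, v, s2e, method)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    if not k_free:
        # residual-only face: closed form (OLS residual variance)
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        dof = n - p if method == "REML" else n
        s2e = max(rss / dof, s2e_floor)
        ll, beta, cov = _gaussian_loglik(y, X, Z_blocks, [0.0] * len(Z_blocks), s2e, method)
        return [0.0] * len(Z_blocks), s2e, ll, beta, cov, True

    theta0 = np.log([max(starts[k], 1e-12) for k in k_free] + [max(starts[-1], 1e-12)])
    res = optimize.minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 8000, "maxfev": 8000},
    )
    v, s2e = unpack(res.x)
    try:
        ll, beta, cov = _gaussian_loglik(y, X, Z_blocks, v, s2e, method)
    except np.linalg.LinAlgError:
        return None
    return v, s2e, ll, beta, cov, bool(res.success)


def _fit_mixed(y, X, Z_blocks, method):
    """Best fit over all boundary faces of the non-negativity constraint."""
    starts = _moment_starts(y, Z_blocks)
    best = None
    k = len(Z_blocks)
    for mask in range(2**k):
        free = [bool(mask >> i & 1) for i in range(k)]
        out = _maximize_face(y, X, Z_blocks, free, method, starts)
        if out is not None and (best is None or out[2] > best[2] + 1e-10):
            best = out
    if best is None:
        raise np.linalg.LinAlgError("no boundary face yielded a usable fit")
    v, s2e, ll, beta, cov, ok = best
    # components estimated numerically at ~0 are exact boundary solutions
    v = [0.0 if vi < 1e-10 * (s2e + sum(v)) else vi for vi in v]
    try:
        ll, beta, cov = _gaussian_loglik(y, X, Z_blocks, v, s2e, method)
    except np.linalg.LinAlgError:
        v, s2e, ll, beta, cov, ok = best
    return v, s2e, ll, beta, cov, ok


def fit_random_model(y, provenance, block, method="REML") -> RandomModelFit:
    """REML (or ML) estimates of (σ²_inter, σ²_block, σ²_intra) for one trait.

    Boundary solutions (zero variance components) are found by explicit
    maximization over every zero-variance face; the grand mean μ is the GLS
    mean at the estimated covariance.
    """
    y = np.asarray(y, dtype=float)
    prov = np.asarray(provenance)
    blk = np.asarray(block)
    if len(np.unique(prov)) < 2 or len(np.unique(blk)) < 2:
        raise ValueError("need at least 2 provenances and 2 blocks")
    X = np.ones((len(y), 1))
    Z_blocks = [_indicator(prov), _indicator(blk)]
    v, s2e, ll, beta, _, ok = _fit_mixed(y, X, Z_blocks, method)
    return RandomModelFit(
        mu=float(beta[0]),
        sigma2_inter=v[0],
        sigma2_block=v[1],
        sigma2_intra=s2e,
        loglik=ll,
        method=method,
        converged=ok,
    )


def fit_block_only_model(y, provenance, block, method="REML") -> RandomModelFit:
    """The reduced model without the provenance component (LRT null)."""
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    Z_blocks = [_indicator(block)]
    v, s2e, ll, beta, _, ok = _fit_mixed(y, X, Z_blocks, method)
    return RandomModelFit(
        mu=float(beta[0]),
        sigma2_inter=0.0,
        sigma2_block=v[0],
        sigma2_intra=s2e,
        loglik=ll,
        method=method,
        converged=ok,
        components=("block",),
    )


def lrt_provenance(full: RandomModelFit, reduced: RandomModelFit):
    """Boundary-corrected LRT of σ²_inter = 0.

    Returns (LR, Δ_i, p_corrected) with LR = 2(ll_full − ll_reduced) clipped
    at 0, Δ_i = LR − 2 (the AIC difference for the one extra variance), and
    p_corrected = 0.5 × P(χ²₁ ≥ LR).  At LR = 0 the corrected p is exactly
    0.5, the largest value the mixture null can produce.
    """
    if full.method != reduced.method:
        raise ValueError("full and reduced fits must use the same method")
    lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p_corrected = 0.5 * float(stats.chi2.sf(lr, df=1))
    return lr, lr - 2.0, p_corrected


def cv_components(y, provenance, intra: str = "mean") -> tuple[float, float]:
    """Coefficients of variation between and within provenances (%).

    CV_inter = SD of provenance means / grand mean × 100.  CV_intra averages
    the within-provenance sample SDs over provenances (``intra="mean"``) or
    pools them (``intra="pooled"``, √ of the df-weighted mean within-variance)
    before dividing by the grand mean.  Sample (n−1) SDs throughout.
    """
    y = np.asarray(y, dtype=float)
    prov = np.asarray(provenance)
    grand = float(np.mean(y))
    if grand == 0:
        raise ValueError("grand mean is zero; CV undefined")
    groups = [y[prov == g] for g in pd.unique(prov)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need ≥2 provenances with ≥2 observations each")
    means = np.array([g.mean() for g in groups])
    cv_inter = float(np.std(means, ddof=1)) / abs(grand) * 100.0
    if intra == "mean":
        sd_within = float(np.mean([np.std(g, ddof=1) for g in groups]))
    elif intra == "pooled":
        num = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups)
        den = sum(len(g) - 1 for g in groups)
        sd_within = float(np.sqrt(num / den))
    else:
        raise ValueError(f"intra must be 'mean' or 'pooled', got {intra!r}")
    return cv_inter, sd_within / abs(grand) * 100.0


def variance_component_percents(fit: RandomModelFit) -> tuple[float, float, float]:
    """(VC_inter, VC_block, VC_intra): each σ² as % of the total; sums to 100."""
    total = fit.sigma2_inter + fit.sigma2_block + fit.sigma2_intra
    if total <= 0:
        raise ValueError("all variance components are zero; percentages undefined")
    return (
        fit.sigma2_inter / total * 100.0,
        fit.sigma2_block / total * 100.0,
        fit.sigma2_intra / total * 100.0,
    )


def variance_partition_summary(trait, y, provenance, block, intra="mean") -> VarCompSummary:
    """One trait's full decomposition: CVs, VC %, and the corrected LRT."""
    y = np.asarray(y, dtype=float)
    full = fit_random_model(y, provenance, block, method="REML")
    reduced = fit_block_only_model(y, provenance, block, method="REML")
    lr, d_aic, p = lrt_provenance(full, reduced)
    vc = variance_component_percents(full)
    cv_i, cv_w = cv_components(y, provenance, intra=intra)
    return VarCompSummary(
        trait=trait,
        n=len(y),
        cv_inter=cv_i,
        cv_intra=cv_w,
        vc_inter=vc[0],
        vc_block=vc[1],
        vc_intra=vc[2],
        lr=lr,
        delta_aic=d_aic,
        p_corrected=p,
    )


def fit_climate_model(
    y, fai_by_provenance, provenance, block, log_transform: bool = False
) -> ClimateModelFit:
    """ML fit of the FAI climate model with a χ²₁ LRT on the slope β.

    ``fai_by_provenance`` maps provenance label → FAI at origin (constant
    within provenance by construction).  When ``log_transform`` is set, the
    response is natural-log transformed before fitting, as done for the
    right-skewed traits in :data:`LOG_TRANSFORM_TRAITS`.  Fixed effects are
    compared under ML (REML likelihoods with different X are incommensurable).
    """
    y = np.asarray(y, dtype=float)
    prov = np.asarray(provenance)
    fai = np.array([fai_by_provenance[p] for p in prov], dtype=float)
    if np.ptp(fai) == 0:
        raise ValueError("FAI is constant across provenances; slope inestimable")
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive trait values")
        y = np.log(y)

    Z_blocks = [_indicator(prov), _indicator(np.asarray(block))]
    X_full = np.column_stack([np.ones(len(y)), fai])
    X_null = np.ones((len(y), 1))

    v, s2e, ll_full, beta, cov, ok = _fit_mixed(y, X_full, Z_blocks, "ML")
    _, _, ll_null, _, _, _ = _fit_mixed(y, X_null, Z_blocks, "ML")

    lr = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(stats.chi2.sf(lr, df=1))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return ClimateModelFit(
        alpha=float(beta[0]),
        beta=float(beta[1]),
        se_alpha=float(se[0]),
        se_beta=float(se[1]),
        sd_prov=float(np.sqrt(v[0])),
        sd_block=float(np.sqrt(v[1])),
        sd_resid=float(np.sqrt(s2e)),
        loglik=ll_full,
        lr=lr,
        delta_aic=lr - 2.0,
        p=p,
        n=len(y),
        converged=ok,
        log_transformed=log_transform,
    )
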