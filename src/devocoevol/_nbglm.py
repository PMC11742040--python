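"""Negative-binomial GLM fitting with a fixed, gene-level dispersion.

Log link with a log size-factor offset; NB2 variance mu + alpha*mu^2.
The dispersion alpha is a nuisance parameter estimated once per gene
under the fullest design and then held fixed across all nested fits, so
that likelihood-ratio statistics between nested mean models are valid.

Fitting is plain IRLS with step halving; for alpha -> 0 the fit
coincides with a Poisson GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

ALPHA_FLOOR = 1e-8
ALPHA_CAP = 10.0


class FitError(RuntimeError):
    """IRLS failed to converge or the design is unusable."""


@dataclass
class NBFit:
    coef: np.ndarray
    loglik: float
    df: int
    mu: np.ndarray
    alpha: float
    converged: bool


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Exact NB2 log-likelihood (Poisson in the alpha -> 0 limit).

    For near-Poisson dispersions (r = 1/alpha >= 1e7) the gammaln
    difference is evaluated by its series in y/r: the direct difference of
    two O(r log r) gammaln values loses ~1e-6 of absolute precision, enough
    to destabilize likelihood comparisons between IRLS steps.
    """
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-300)
    r = 1.0 / alpha
    if r >= 1e7:
        # log Gamma(y+r) - log Gamma(r) = sum_{k<y} log(r+k), expanded in k/r
        lg = (y * np.log(r) + y * (y - 1) / (2 * r)
              - y * (y - 1) * (2 * y - 1) / (12 * r ** 2))
    else:
        lg = gammaln(y + r) - gammaln(r)
    log_rpm = np.log(r) + np.log1p(mu / r)
    # r*log(r/(r+mu)) via log1p: the naive difference cancels catastrophically
    return float(np.sum(
        lg - gammaln(y + 1) - r * np.log1p(mu / r) + y * (np.log(mu) - log_rpm)
    ))


def check_full_rank(X: np.ndarray) -> None:
    if X.shape[1] > X.shape[0]:
        raise FitError(f"design has more columns ({X.shape[1]}) than rows ({X.shape[0]})")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        q, r = np.linalg.qr(X)
        bad = np.where(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())[0]
        raise FitError(f"rank-deficient design: collinear columns {bad.tolist()}")


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray | float = 1.0,
    alpha: float = ALPHA_FLOOR,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    check_rank: bool = True,
) -> NBFit:
    """Maximum-likelihood NB GLM with log link and log(size_factor) offset.

    Returns coefficients, the exact NB log-likelihood and the model df
    (number of columns). Raises FitError on rank deficiency or
    non-convergence after damped retries.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if check_rank:
        check_full_rank(X)
    offset = np.log(np.broadcast_to(np.asarray(size_factors, float), y.shape))
    alpha = float(np.clip(alpha, ALPHA_FLOOR, ALPHA_CAP))

    mu = np.maximum(y, 0.0) + 0.5
    eta = np.log(mu)
    beta, *_ = np.linalg.lstsq(X, eta - offset, rcond=None)
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    ll = nb_loglik(y, mu, alpha)

    converged = False
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)          # mu^2 / V(mu)
        z = (eta - offset) + (y - mu) / mu   # working response
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = beta_new - beta
        # step halving if the likelihood does not improve
        ll_new, mu_new, eta_new = -np.inf, mu, eta
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand + offset
            mu_c = np.exp(np.clip(eta_c, -30, 30))
            ll_c = nb_loglik(y, mu_c, alpha)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-9 * (1.0 + abs(ll)):
                beta_new, ll_new, mu_new, eta_new = cand, ll_c, mu_c, eta_c
                break
            scale *= 0.5
        else:
            raise FitError("IRLS diverged: no improving damped step found")
        delta = abs(ll_new - ll)
        step_size = float(np.abs(beta_new - beta).max())
        beta, ll, mu, eta = beta_new, ll_new, mu_new, eta_new
        # coefficient-level criterion: the log-likelihood flattens out long
        # before the coefficients reach full precision
        if step_size <= tol * (1.0 + float(np.abs(beta).max())):
            converged = True
            break
    if not converged:
        raise FitError(f"IRLS did not converge in {max_iter} iterations "
                       f"(|dll|={delta:.3g}, |dbeta|={step_size:.3g})")
    return NBFit(coef=beta, loglik=ll, df=X.shape[1], mu=mu, alpha=alpha, converged=True)


def estimate_dispersion(
    y: np.ndarray,
    X: np.ndarray,
    size_factors: np.ndarray | float = 1.0,
    *,
    cox_reid: bool = True,
) -> float:
    """Per-gene dispersion under the given (fullest) design.

    Maximizes the Cox-Reid adjusted profile likelihood over log(alpha)
    (the -0.5*logdet(X'WX) adjustment removes the severe downward bias of
    plain ML when the mean model has many parameters relative to the sample
    count). Floored at 1e-8 and capped at 10. All-zero genes are not
    estimable and raise FitError (callers exclude such genes from testing).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if np.all(y == 0):
        raise FitError("all-zero gene: dispersion not estimable")

    def neg_profile(log_alpha: float) -> float:
        alpha = np.exp(log_alpha)
        try:
            fit = fit_nb_glm(y, X, size_factors, alpha, check_rank=False)
        except FitError:
            return np.inf
        obj = fit.loglik
        if cox_reid:
            w = fit.mu / (1.0 + alpha * fit.mu)
            sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            if sign <= 0:
                return np.inf
            obj -= 0.5 * logdet
        return -obj

    res = minimize_scalar(neg_profile, bounds=(np.log(ALPHA_FLOOR), np.log(ALPHA_CAP)),
                          method="bounded", options={"xatol": 5e-3})
    alpha = float(np.exp(res.x))
    # snap to the boundary when the optimum sits on it
    if neg_profile(np.log(ALPHA_FLOOR)) <= res.fun + 1e-9:
        alpha = ALPHA_FLOOR
    return float(np.clip(alpha, ALPHA_FLOOR, ALPHA_CAP))


def dispersion_curvature(y: np.ndarray, X: np.ndarray, size_factors, alpha: float,
                         h: float = 0.15) -> float:
    """Observed information of the CR-adjusted profile in log(alpha).

    Numeric second difference; used as the inverse sampling variance of
    log(alpha_hat) when moderating dispersions across genes.
    """
    la = np.log(np.clip(alpha, ALPHA_FLOOR * 2, ALPHA_CAP / 2))

    def apl(lv: float) -> float:
        a = float(np.exp(lv))
        fit = fit_nb_glm(y, X, size_factors, a, check_rank=False)
        w = fit.mu / (1.0 + a * fit.mu)
        _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        return fit.loglik - 0.5 * logdet

    try:
        info = -(apl(la + h) - 2.0 * apl(la) + apl(la - h)) / h ** 2
    except FitError:
        return 0.0
    return max(float(info), 0.0)


def common_dispersion(ys: list[np.ndarray], X: np.ndarray, size_factors,
                      max_genes: int = 400) -> float:
    """Cohort-common dispersion: maximizes the summed CR-adjusted profile.

    Pooling across genes removes the per-gene estimation noise (and, with
    the Cox-Reid adjustment, the leading small-sample bias); used as the
    shrinkage target when moderating per-gene dispersions. For large
    cohorts a deterministic thinning to `max_genes` genes keeps the cost
    bounded.
    """
    if len(ys) > max_genes:
        step = int(np.ceil(len(ys) / max_genes))
        ys = ys[::step]

    def neg(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        total = 0.0
        for y in ys:
            try:
                fit = fit_nb_glm(y, X, size_factors, alpha, check_rank=False)
            except FitError:
                continue
            w = fit.mu / (1.0 + alpha * fit.mu)
            sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            if sign <= 0:
                return np.inf
            total += fit.loglik - 0.5 * logdet
        return -total

    res = minimize_scalar(neg, bounds=(np.log(ALPHA_FLOOR), np.log(ALPHA_CAP)),
                          method="bounded", options={"xatol": 2e-3})
    return float(np.clip(np.exp(res.x), ALPHA_FLOOR, ALPHA_CAP))


def moderate_dispersions(alphas: np.ndarray, infos: np.ndarray, center: float) -> np.ndarray:
    """Empirical-Bayes shrinkage of per-gene log-dispersions.

    Normal-normal moderation on the log scale: each gene's estimate has
    sampling variance 1/info; the prior variance is the excess of the
    observed spread over the average sampling variance; the prior mean is
    the cohort-common dispersion. Genes with flat profiles (info ~ 0, e.g.
    Poisson-like genes at the floor) shrink fully to the center, which errs
    on the conservative side for the LRTs.
    """
    alphas = np.asarray(alphas, float)
    infos = np.asarray(infos, float)
    x = np.log(np.clip(alphas, ALPHA_FLOOR, ALPHA_CAP))
    c = np.log(np.clip(center, ALPHA_FLOOR, ALPHA_CAP))
    s2 = 1.0 / np.clip(infos, 1e-3, np.inf)
    ok = infos > 1e-3
    spread = float(np.var(x[ok])) if ok.any() else 0.0
    tau2 = max(spread - (float(np.mean(s2[ok])) if ok.any() else 0.0), 0.0)
    post = (tau2 * x + s2 * c) / (tau2 + s2)
    return np.exp(np.clip(post, np.log(ALPHA_FLOOR), np.log(ALPHA_CAP)))
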