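"""Binomial GLM fitting with arbitrary (notably power-odds) links.

The power-odds link applied directly to the case-control probabilities is
closed under case-control sampling up to a rescaling of the coefficients, so
the exponent ``lam`` can be profiled out of a retrospective study without
knowing the sampling ratio: for each ``lam`` on a grid the regression is fit
by iteratively reweighted least squares (IRLS), and the profile
log-likelihood traced over the grid locates the maximum-likelihood ``lam``
and a likelihood-ratio confidence set.

IRLS here is guarded: the power-odds link is non-canonical and a full Newton
step can overshoot into fitted probabilities outside (0, 1) or decrease the
likelihood, so each step is halved until the likelihood does not decrease
and all fitted values stay inside (eps, 1 - eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .links import LinkSpec, make_link

__all__ = ["GLMFit", "ProfileLikelihood", "fit_glm", "profile_lambda"]

_MU_EPS = 1e-10


@dataclass
class GLMFit:
    coef: np.ndarray
    loglik: float
    fitted: np.ndarray
    link: str
    converged: bool
    n_iter: int
    warnings: list = field(default_factory=list)


@dataclass
class ProfileLikelihood:
    """Profile log-likelihood of the power-odds exponent.

    ``loglik[i]`` is the Bernoulli log-likelihood maximized over the
    regression coefficients at ``lambda_grid[i]``; ``lambda_mle`` refines the
    grid argmax by a local quadratic fit; ``ci`` is the contiguous
    likelihood-ratio confidence interval at ``level`` (the grid points
    satisfying ``2 (max - loglik) <= chi2_1(level)``, reported as the set of
    grid points if non-contiguous).
    """

    lambda_grid: np.ndarray
    loglik: np.ndarray
    lambda_mle: float
    loglik_max: float
    ci: tuple
    level: float
    excluded: list = field(default_factory=list)

    def contains(self, lam: float) -> bool:
        """Whether ``lam`` lies in the confidence set (interval endpoints
        inclusive, with an epsilon for grid round-off)."""
        lo, hi = self.ci
        return lo - 1e-9 <= lam <= hi + 1e-9

    def to_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid.tolist(),
            "loglik": self.loglik.tolist(),
            "lambda_mle": self.lambda_mle,
            "loglik_max": self.loglik_max,
            "ci": list(self.ci),
            "level": self.level,
            "excluded": list(self.excluded),
        }


def _bernoulli_loglik(y, mu):
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return float(y @ np.log(mu) + (1.0 - y) @ np.log1p(-mu))


def fit_glm(y, design, link: LinkSpec, max_iter: int = 100,
            tol: float = 1e-10, start: np.ndarray | None = None) -> GLMFit:
    """Maximum-likelihood fit of a Bernoulli GLM by step-halved IRLS.

    Parameters
    ----------
    y : (n,) 0/1 array
    design : (n, p) full-rank covariate matrix (include the intercept column)
    link : LinkSpec
    start : optional initial coefficient vector; by default the intercept is
        initialized at ``g(mean(y))`` and slopes at zero.

    Convergence is declared when the relative change in log-likelihood falls
    below ``tol``.  Non-convergence and near-separation (fitted values pinned
    at the boundary) are flagged in ``warnings`` rather than raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    if start is not None:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(p)
        ybar = np.clip(y.mean(), _MU_EPS, 1 - _MU_EPS)
        # assumes an intercept-like column; harmless otherwise
        const = np.where(np.ptp(X, axis=0) == 0)[0]
        if const.size:
            j = const[0]
            beta[j] = float(link.g(ybar)) / X[0, j]

    def mu_of(b):
        return np.clip(link.g_inverse(X @ b), _MU_EPS, 1.0 - _MU_EPS)

    mu = mu_of(beta)
    ll = _bernoulli_loglik(y, mu)
    converged = False
    it = 0
    warnings = []
    for it in range(1, max_iter + 1):
        # dg/dmu = g'(mu); working weights 1/(g'(mu)^2 mu(1-mu))
        gp = link.g_prime(mu)
        var = mu * (1.0 - mu)
        w = 1.0 / (gp * gp * var)
        eta = X @ beta
        zwork = eta + (y - mu) * gp
        WX = X * w[:, None]
        try:
            delta = np.linalg.solve(X.T @ WX, WX.T @ zwork) - beta
        except np.linalg.LinAlgError:
            warnings.append("singular working weight matrix")
            break
        # step halving: accept the largest step that does not decrease loglik
        step = 1.0
        accepted = False
        for _ in range(40):
            cand = beta + step * delta
            mu_c = mu_of(cand)
            ll_c = _bernoulli_loglik(y, mu_c)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-13 * max(1.0, abs(ll)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no uphill step exists: at a (local) maximum
            break
        rel = abs(ll_c - ll) / max(1.0, abs(ll))
        beta, mu, ll = cand, mu_c, ll_c
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.append(f"IRLS did not converge in {max_iter} iterations")
    pinned = np.mean((mu <= 2 * _MU_EPS) | (mu >= 1 - 2 * _MU_EPS))
    if pinned > 0.01:
        warnings.append(f"possible separation: {pinned:.1%} fitted values at the boundary")
    return GLMFit(beta, ll, mu, link.label, converged, it, warnings)


def profile_lambda(y, design, lambda_grid=None, level: float = 0.95) -> ProfileLikelihood:
    """Profile log-likelihood of the power-odds exponent over a grid.

    At each grid ``lam`` the model ``g_lam(mu) = design @ beta`` is fit to the
    case-control data directly (no sampling-ratio correction is needed: the
    family maps onto itself under case-control sampling).  The MLE refines
    the grid argmax by a quadratic through the three bracketing points, and
    the confidence set collects grid points within the chi-squared(1)
    likelihood-ratio cutoff.
    """
    if lambda_grid is None:
        lambda_grid = np.arange(-0.3, 0.5001, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size < 3:
        raise ValueError("lambda grid must cover at least 3 points")
    lambda_grid = np.sort(lambda_grid)

    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    lls = np.full(lambda_grid.size, np.nan)
    excluded = []
    start = None
    for i, lam in enumerate(lambda_grid):
        fit = fit_glm(y, X, make_link("power_odds", lam), start=None if start is None else start)
        if not fit.converged:
            excluded.append(float(lam))
            continue
        lls[i] = fit.loglik
        start = fit.coef  # warm start: profiles are smooth in lam

    ok = np.isfinite(lls)
    if ok.sum() < 3:
        raise RuntimeError("fewer than 3 grid points converged")
    grid, ll = lambda_grid[ok], lls[ok]
    j = int(np.argmax(ll))
    lam_mle, ll_max = float(grid[j]), float(ll[j])
    if 0 < j < grid.size - 1:
        # quadratic refinement through the bracketing triple
        x0, x1, x2 = grid[j - 1:j + 2]
        f0, f1, f2 = ll[j - 1:j + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (f1 - f0) + x1 * (f0 - f2) + x0 * (f2 - f1)) / denom
        b = (x2 * x2 * (f0 - f1) + x1 * x1 * (f2 - f0) + x0 * x0 * (f1 - f2)) / denom
        if a < 0:
            xv = -b / (2 * a)
            cand = float(a * xv * xv + b * xv + (f0 - a * x0 * x0 - b * x0))
            # reject unstable refinements (near-collinear triples can place
            # the fitted vertex far above the evaluated profile)
            if x0 < xv < x2 and cand <= f1 + 1.0:
                lam_mle = float(xv)
                ll_max = cand
    cut = stats.chi2.ppf(level, df=1) / 2.0
    inset = grid[ll_max - ll <= cut]
    ci = (float(inset.min()), float(inset.max()))
    return ProfileLikelihood(grid, ll, lam_mle, ll_max, ci, level, excluded)
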