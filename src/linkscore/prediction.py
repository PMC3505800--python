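"""Heritability-to-predictability calculations under four multi-locus models.

How well disease status could ever be predicted from a complete genotype
score depends on the scale on which risks accumulate.  Holding fixed the two
observable summaries — the population risk ``P`` and the sibling recurrence
risk ratio ``lambda_S`` (risk to a sibling of a case over ``P``) — the four
models below give very different receiver operating characteristic (ROC)
curves:

* **multiplicative (log link)** — a genetic score ``x ~ N(0,1)`` with
  ``risk = exp(c0 + alpha x)``; sibling scores are bivariate normal with
  correlation 1/2, giving the closed form ``lambda_S = exp(alpha^2 / 2)``.
  The score among cases is ``N(alpha, 1)`` (exponential tilting).
* **independent sufficient causes** — a Poisson(mu) count of rare,
  individually sufficient variants with penetrance ``p`` each and sporadic
  background risk ``b``; additivity on ``-log(1 - risk)``.  Sibling counts
  share a Poisson(mu/2) component.
* **quadratic-log** — ``log risk = c0 + c1 x + c2 x^2``, the small-exponent
  expansion of a power transform of risk; ``c2 < 0`` is sub-multiplicative
  (risk accumulating more slowly than the log-linear model in its upper
  tail), ``c2 > 0`` supra-multiplicative.
* **probit (liability threshold)** — disease when a standard-normal
  liability exceeds ``T = Phi^{-1}(1 - P)``; heritability ``H`` is the
  variance share of the genetic score, sibling liabilities correlate
  ``H/2``, and the score-liability correlation is ``sqrt(H)``.

All closed forms here are guarded by Monte-Carlo sibling-pair oracles in the
test suite (see :mod:`linkscore.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm, poisson

__all__ = [
    "ROCCurve",
    "bvn_upper",
    "loglink_lambda_s",
    "loglink_alpha_from_lambda_s",
    "loglink_roc",
    "ISCModel",
    "isc_population_risk",
    "isc_lambda_s",
    "isc_roc",
    "isc_model_from",
    "probit_lambda_s",
    "probit_H_from_lambda_s",
    "probit_roc",
    "quadlog_lambda_s",
    "quadlog_roc",
    "quadlog_c1_from_lambda_s",
]


@dataclass
class ROCCurve:
    """Ordered operating points from (0,0) to (1,1) with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float = field(init=False)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        order = np.argsort(fpr, kind="stable")
        fpr, tpr = fpr[order], tpr[order]
        # prepend/append the trivial corners and enforce monotone tpr
        fpr = np.concatenate([[0.0], fpr, [1.0]])
        tpr = np.concatenate([[0.0], tpr, [1.0]])
        tpr = np.maximum.accumulate(np.clip(tpr, 0.0, 1.0))
        fpr = np.clip(fpr, 0.0, 1.0)
        self.fpr, self.tpr = fpr, tpr
        self.auc = float(np.trapezoid(tpr, fpr))


def bvn_upper(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho.

    Evaluated as ``int_h^inf phi(x) Phi((rho x - k)/sqrt(1-rho^2)) dx`` by
    adaptive quadrature; absolute accuracy well below 1e-7 over the
    parameter ranges used here.
    """
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return float(ndtr(-max(h, k)))
        return float(max(0.0, ndtr(-h) - ndtr(k)))
    if rho == 0.0:
        return float(ndtr(-h) * ndtr(-k))
    s = np.sqrt(1.0 - rho * rho)

    def integrand(x):
        return norm.pdf(x) * ndtr((rho * x - k) / s)

    hi = max(h + 10.0, 10.0)
    val, _ = integrate.quad(integrand, h, hi, epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# multiplicative (log link) model


def loglink_lambda_s(alpha: float) -> float:
    """Sibling recurrence ratio of the log-link model.

    With ``risk = exp(c0 + alpha x)`` and sibling scores bivariate normal
    with correlation 1/2, ``E[risk1 risk2] / P^2 = exp(alpha^2 rho)`` at
    ``rho = 1/2``, i.e. ``lambda_S = exp(alpha^2 / 2)`` — independent of P.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return float(np.exp(0.5 * alpha * alpha))


def loglink_alpha_from_lambda_s(lambda_s: float) -> float:
    if lambda_s < 1.0:
        raise ValueError("lambda_S must be at least 1")
    return float(np.sqrt(2.0 * np.log(lambda_s)))


def _loglink_c0(alpha: float, P: float) -> float:
    # marginal risk E[exp(c0 + alpha x)] = exp(c0 + alpha^2/2) = P
    return np.log(P) - 0.5 * alpha * alpha


def loglink_roc(alpha: float, P: float, n_grid: int = 4001) -> ROCCurve:
    """Analytic ROC of the log-link model at effect ``alpha`` and prevalence ``P``.

    Case scores are ``N(alpha, 1)``; the non-case density is
    ``(1 - risk(x)) phi(x) / (1 - P)``, integrated numerically on a wide
    grid.  ``extras['fraction_risk_above_one']`` reports the population
    fraction whose nominal risk exceeds 1 (the model's known pathology at
    large effect sizes); the analytic curve ignores the cap, which is
    negligible whenever that fraction is.
    """
    if not 0.0 < P < 1.0:
        raise ValueError("P must lie in (0, 1)")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0.0:
        return ROCCurve(np.linspace(0, 1, 11), np.linspace(0, 1, 11),
                        extras={"fraction_risk_above_one": 0.0})
    c0 = _loglink_c0(alpha, P)
    lo, hi = -9.0, max(9.0, alpha + 9.0)
    x = np.linspace(lo, hi, n_grid)
    risk = np.exp(c0 + alpha * x)
    noncase_density = (1.0 - np.minimum(risk, 1.0)) * norm.pdf(x) / (1.0 - P)
    # survival function of x among non-cases on the grid (right tail mass)
    dx = x[1] - x[0]
    cdf = np.concatenate([[0.0], np.cumsum((noncase_density[1:] + noncase_density[:-1]) * 0.5 * dx)])
    sf_noncase = np.clip(cdf[-1] - cdf, 0.0, 1.0) / max(cdf[-1], 1e-300)
    tpr = ndtr(alpha - x)          # P(N(alpha,1) > x)
    frac_over = float(ndtr(-(np.log(1.0 / P) + 0.5 * alpha * alpha) / alpha))
    return ROCCurve(sf_noncase, tpr, extras={"fraction_risk_above_one": frac_over})


# ---------------------------------------------------------------------------
# independent sufficient causes model


@dataclass(frozen=True)
class ISCModel:
    """Poisson count of sufficient risk variants plus sporadic background.

    ``mu``: expected variant count; ``p``: penetrance of one variant acting
    alone; ``b``: non-heritable sporadic risk, itself an independent
    sufficient cause.  A subject with count ``x`` has
    ``risk = 1 - (1 - b)(1 - p)^x``.
    """

    mu: float
    p: float
    b: float = 0.0

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0.0 <= self.p <= 1.0 or not 0.0 <= self.b <= 1.0:
            raise ValueError("p and b must lie in [0, 1]")

    def risk(self, x):
        return 1.0 - (1.0 - self.b) * (1.0 - self.p) ** np.asarray(x)


def isc_population_risk(model: ISCModel) -> float:
    """Marginal risk ``P = 1 - (1 - b) exp(-mu p)`` via the Poisson generating function."""
    return float(1.0 - (1.0 - model.b) * np.exp(-model.mu * model.p))


def isc_lambda_s(model: ISCModel) -> float:
    """Sibling recurrence ratio from the shared/unshared Poisson decomposition.

    Sibling counts are ``x_i = s + u_i`` with ``s, u_1, u_2`` independent
    Poisson(mu/2).  Joint unaffected probability uses the generating
    function ``E[(1-p)^{2s + u_1 + u_2}] = exp(-2 mu p + mu p^2 / 2)``:

        P(both) = 1 - 2(1-b) e^{-mu p} + (1-b)^2 e^{-2 mu p + mu p^2 / 2}

    and ``lambda_S = P(both) / P^2``.
    """
    P = isc_population_risk(model)
    if P <= 0.0:
        raise ValueError("population risk is zero; lambda_S undefined")
    mu, p, b = model.mu, model.p, model.b
    both = (1.0 - 2.0 * (1.0 - b) * np.exp(-mu * p)
            + (1.0 - b) ** 2 * np.exp(-2.0 * mu * p + 0.5 * mu * p * p))
    return float(both / (P * P))


def _isc_support(mu: float) -> np.ndarray:
    xmax = int(max(10, poisson.isf(1e-14, mu))) if mu > 0 else 0
    return np.arange(0, xmax + 1)


def isc_roc(model: ISCModel) -> ROCCurve:
    """Exact ROC of the variant count as a risk score, thresholds at integers.

    Operating points are linearly interpolated between attainable integer
    thresholds.  ``extras`` reports the mean count among cases and
    non-cases.
    """
    P = isc_population_risk(model)
    x = _isc_support(model.mu)
    px = poisson.pmf(x, model.mu) if model.mu > 0 else np.array([1.0])
    risk = model.risk(x)
    p_case = px * risk
    p_ctrl = px * (1.0 - risk)
    if P <= 0.0 or P >= 1.0:
        raise ValueError("degenerate population risk")
    # threshold k: call positive when x >= k, k = 0 .. xmax+1
    tail_case = np.concatenate([np.cumsum(p_case[::-1])[::-1], [0.0]]) / P
    tail_ctrl = np.concatenate([np.cumsum(p_ctrl[::-1])[::-1], [0.0]]) / (1.0 - P)
    extras = {
        "mean_count_cases": float(np.sum(x * p_case) / P),
        "mean_count_noncases": float(np.sum(x * p_ctrl) / (1.0 - P)),
        "population_risk": P,
    }
    return ROCCurve(tail_ctrl, tail_case, extras=extras)


def isc_model_from(P: float, lambda_s: float, b: float = 0.0) -> ISCModel:
    """Solve (mu, p) so the model matches a target prevalence and lambda_S.

    With ``b`` fixed, ``mu`` is eliminated through the prevalence identity
    ``mu = -log((1-P)/(1-b)) / p`` and the remaining one-dimensional root in
    ``p`` is bracketed on (0, 1]; lambda_S rises monotonically with ``p``
    (fewer, more penetrant variants = more locus heterogeneity).
    """
    if not 0.0 < P < 1.0 or lambda_s < 1.0 or not 0.0 <= b < 1.0:
        raise ValueError("need P in (0,1), lambda_s >= 1, b in [0,1)")
    if b >= P:
        raise ValueError("background risk b must be below the target prevalence")
    target_mup = np.log((1.0 - b) / (1.0 - P))  # = mu * p

    def lam_at(p):
        return isc_lambda_s(ISCModel(target_mup / p, p, b))

    if lam_at(1.0) < lambda_s:
        raise ValueError("lambda_s unattainable at this prevalence/background")
    lo = 1e-8
    if lam_at(lo) > lambda_s:
        raise ValueError("lambda_s below the weak-heterogeneity limit")
    p = brentq(lambda q: lam_at(q) - lambda_s, lo, 1.0, xtol=1e-12)
    return ISCModel(target_mup / p, float(p), b)


# ---------------------------------------------------------------------------
# probit / liability threshold model


def probit_lambda_s(H: float, P: float) -> float:
    """Sibling recurrence ratio of the liability threshold model.

    ``lambda_S = Phi2(L1 > T, L2 > T; rho = H/2) / P^2`` with
    ``T = Phi^{-1}(1 - P)``.
    """
    if not 0.0 <= H <= 1.0:
        raise ValueError("heritability H must lie in [0, 1]")
    if not 0.0 < P < 1.0:
        raise ValueError("P must lie in (0, 1)")
    T = ndtri(1.0 - P)
    return bvn_upper(T, T, H / 2.0) / (P * P)


def probit_H_from_lambda_s(lambda_s: float, P: float) -> float:
    """Invert ``lambda_S(H)`` at fixed prevalence by bracketed root-finding."""
    if lambda_s < 1.0:
        raise ValueError("lambda_S must be at least 1")
    lam_max = probit_lambda_s(1.0, P)
    if lambda_s > lam_max * (1 + 1e-12):
        raise ValueError(
            f"lambda_S={lambda_s:g} unattainable at P={P:g} (max {lam_max:.4g} at H=1)")
    if lambda_s == 1.0:
        return 0.0
    return float(brentq(lambda h: probit_lambda_s(h, P) - lambda_s,
                        0.0, 1.0, xtol=1e-12))


def _roc_threshold_grid():
    # dense central grid plus far-tail points so tiny-P curves resolve
    u = np.concatenate([
        np.linspace(1e-12, 1 - 1e-12, 801),
        np.logspace(-12, -0.31, 120),
        1.0 - np.logspace(-12, -0.31, 120),
    ])
    return np.unique(ndtri(np.clip(u, 1e-15, 1 - 1e-15)))


def probit_roc(H: float, P: float) -> ROCCurve:
    """Analytic ROC of the genetic score under the liability threshold model.

    The score ``g`` correlates ``sqrt(H)`` with liability, so for a score
    threshold ``t``:

        TPR(t) = Phi2(g > t, L > T; sqrt(H)) / P
        FPR(t) = (Phi(-t) - Phi2(g > t, L > T; sqrt(H))) / (1 - P).
    """
    if not 0.0 <= H <= 1.0:
        raise ValueError("heritability H must lie in [0, 1]")
    if not 0.0 < P < 1.0:
        raise ValueError("P must lie in (0, 1)")
    if H == 0.0:
        return ROCCurve(np.linspace(0, 1, 11), np.linspace(0, 1, 11))
    T = ndtri(1.0 - P)
    rho = np.sqrt(H)
    ts = _roc_threshold_grid()
    joint = np.array([bvn_upper(t, T, rho) for t in ts])
    tpr = np.clip(joint / P, 0.0, 1.0)
    fpr = np.clip((ndtr(-ts) - joint) / (1.0 - P), 0.0, 1.0)
    return ROCCurve(fpr, tpr, extras={"threshold": T, "rho": float(rho)})


# ---------------------------------------------------------------------------
# quadratic-log (power-link approximation) model


def _quad_norm_const(c1: float, c2: float) -> float:
    # E[exp(c1 x + c2 x^2)] for x ~ N(0,1); finite iff c2 < 1/2
    if c2 >= 0.5:
        raise ValueError("non-integrable tilt: need c2 < 1/2")
    s = 1.0 - 2.0 * c2
    return float(np.exp(0.5 * c1 * c1 / s) / np.sqrt(s))


def quadlog_lambda_s(c1: float, c2: float) -> float:
    """Sibling recurrence ratio of the quadratic-log model (exact Gaussian algebra).

    With sibling scores bivariate normal (correlation 1/2) and
    ``risk = exp(c0 + c1 x + c2 x^2)``,
    ``lambda_S = E[risk1 risk2] / P^2`` reduces to a 2-d Gaussian integral
    evaluated in closed form; the intercept cancels, so lambda_S depends on
    (c1, c2) only.  Requires the joint tilt to be integrable.
    """
    rho = 0.5
    Sigma = np.array([[1.0, rho], [rho, 1.0]])
    A = np.diag([c2, c2])
    M = np.eye(2) - 2.0 * Sigma @ A
    det = np.linalg.det(M)
    if det <= 0.0 or c2 >= 0.5:
        raise ValueError("non-integrable sibling tilt")
    bvec = np.array([c1, c1])
    quad = bvec @ np.linalg.solve(M, Sigma @ bvec)
    joint = np.exp(0.5 * quad) / np.sqrt(det)
    single = _quad_norm_const(c1, c2)
    return float(joint / (single * single))


def quadlog_roc(c1: float, c2: float, P: float, n_grid: int = 4001) -> ROCCurve:
    """Analytic ROC of the quadratic-log model, thresholding the score ``x``.

    The case-score density is Gaussian ``N(c1/(1-2c2), 1/(1-2c2))``; the
    non-case tail is integrated numerically.  ``c2 = 0`` reduces exactly to
    :func:`loglink_roc`.  Also reports lambda_S and the fraction of nominal
    risks above 1.
    """
    if not 0.0 < P < 1.0:
        raise ValueError("P must lie in (0, 1)")
    s = 1.0 - 2.0 * c2
    if s <= 0.0:
        raise ValueError("non-integrable tilt: need c2 < 1/2")
    if c1 == 0.0 and c2 == 0.0:
        return ROCCurve(np.linspace(0, 1, 11), np.linspace(0, 1, 11),
                        extras={"lambda_s": 1.0, "fraction_risk_above_one": 0.0})
    c0 = np.log(P) - np.log(_quad_norm_const(c1, c2))
    m, sd = c1 / s, 1.0 / np.sqrt(s)
    lo, hi = min(-9.0, m - 9.0 * sd), max(9.0, m + 9.0 * sd)
    x = np.linspace(lo, hi, n_grid)
    logrisk = c0 + c1 * x + c2 * x * x
    risk = np.exp(np.minimum(logrisk, 0.0))
    noncase_density = (1.0 - risk) * norm.pdf(x) / (1.0 - P)
    dx = x[1] - x[0]
    cdf = np.concatenate([[0.0], np.cumsum((noncase_density[1:] + noncase_density[:-1]) * 0.5 * dx)])
    sf_noncase = np.clip(cdf[-1] - cdf, 0.0, 1.0) / max(cdf[-1], 1e-300)
    tpr = ndtr((m - x) / sd)
    frac_over = float(np.trapezoid(np.where(logrisk > 0.0, norm.pdf(x), 0.0), x))
    return ROCCurve(sf_noncase, tpr,
                    extras={"lambda_s": quadlog_lambda_s(c1, c2),
                            "fraction_risk_above_one": frac_over})


def quadlog_c1_from_lambda_s(lambda_s: float, c2: float) -> float:
    """Solve the linear coefficient so the model hits a target lambda_S at given c2.

    Enables matched-(P, lambda_S) comparisons across curvatures.
    """
    if lambda_s < 1.0:
        raise ValueError("lambda_S must be at least 1")
    base = quadlog_lambda_s(0.0, c2)
    if base > lambda_s:
        raise ValueError("curvature alone already exceeds the target lambda_S")
    hi = 0.5
    while quadlog_lambda_s(hi, c2) < lambda_s:
        hi *= 2.0
        if hi > 64:
            raise ValueError("target lambda_S unattainable")
    return float(brentq(lambda c: quadlog_lambda_s(c, c2) - lambda_s, 0.0, hi, xtol=1e-12))
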