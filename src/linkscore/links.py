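"""Link functions for binomial risk models and their case-control weight functions.

A link ``g`` maps a risk pi in (0, 1) to an unbounded linear-predictor scale
on which covariate effects are assumed additive.  In a case-control study the
population model with link ``g`` induces a modified link on the study-sample
case probability ``mu``, obtained by shifting the odds by the ratio ``K`` of
the sampling fractions of cases and non-cases:

    logit(pi) = logit(mu) - log K.

For a non-canonical link, the efficient score test weights each stratum by

    W(pi) = 1 / (g'(pi) * pi * (1 - pi)),

evaluated at the stratum's population risk.  The weight expressed in study
terms, 1 / (g_CC'(mu) * mu * (1 - mu)), is algebraically identical to W(pi)
at the back-transformed risk, so both parameterizations are exposed.  Weights
are reported unnormalized; every test statistic built on them is invariant to
a global rescaling.

Built-in links (weights follow from the single formula above):

========== ======================= =========================
name        g(pi)                  W(pi)
========== ======================= =========================
logit       log(pi/(1-pi))         1
log         log(pi)                1/(1-pi)
probit      Phi^{-1}(pi)           phi(Phi^{-1}(pi))/(pi(1-pi))
identity    pi                     1/(pi(1-pi))
independence -log(1-pi)            1/pi
power_odds  ((pi/(1-pi))^lam-1)/lam  (pi/(1-pi))^(-lam)
========== ======================= =========================

The power-odds family is the Box-Cox transform of the odds; lam = 0 is the
logit, lam > 0 accumulates risk more slowly than multiplicatively
(sub-multiplicative, low-risk strata up-weighted), lam < 0 faster
(supra-multiplicative, high-risk strata up-weighted).  Its stratum weights
are a pure power of the stratum case:control odds, so the sampling ratio K
never needs to be known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit, logit as _logit, ndtr, ndtri

__all__ = [
    "LinkSpec",
    "make_link",
    "parse_link",
    "cc_transform",
    "weight",
    "cc_weight",
    "powerodds_lambda_matching",
    "LINK_NAMES",
]

# numerical guard: risks are clipped to this open interval before evaluating
# g, g' so tail strata cannot produce inf/nan
_EPS = 1e-12


def _clip(pi):
    return np.clip(np.asarray(pi, dtype=float), _EPS, 1.0 - _EPS)


@dataclass(frozen=True)
class LinkSpec:
    """A population-scale link function with inverse and derivative.

    Attributes
    ----------
    name : str
        Identifier, one of :data:`LINK_NAMES`.
    params : dict
        Real parameters; ``{"lam": float}`` for ``power_odds``, else empty.
    g : callable
        Risk -> linear predictor, vectorized.
    g_inverse : callable
        Linear predictor -> risk, vectorized.
    g_prime : callable
        d g / d pi, strictly positive on (0, 1).
    """

    name: str
    g: Callable[[np.ndarray], np.ndarray]
    g_inverse: Callable[[np.ndarray], np.ndarray]
    g_prime: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.params:
            inner = ",".join(f"{k}={v:g}" for k, v in self.params.items())
            return f"LinkSpec({self.name}:{inner})"
        return f"LinkSpec({self.name})"

    @property
    def label(self) -> str:
        """Config-style name, e.g. ``"power_odds:0.25"``."""
        if self.name == "power_odds":
            return f"power_odds:{self.params['lam']:g}"
        return self.name


def _logit_link() -> LinkSpec:
    return LinkSpec(
        "logit",
        g=lambda p: _logit(_clip(p)),
        g_inverse=lambda e: expit(np.asarray(e, dtype=float)),
        g_prime=lambda p: 1.0 / (_clip(p) * (1.0 - _clip(p))),
    )


def _log_link() -> LinkSpec:
    return LinkSpec(
        "log",
        g=lambda p: np.log(_clip(p)),
        g_inverse=lambda e: np.clip(np.exp(np.asarray(e, dtype=float)), 0.0, 1.0 - _EPS),
        g_prime=lambda p: 1.0 / _clip(p),
    )


def _probit_link() -> LinkSpec:
    def g_prime(p):
        p = _clip(p)
        # 1 / phi(Phi^-1(p)); phi never underflows for clipped p
        z = ndtri(p)
        return np.sqrt(2.0 * np.pi) * np.exp(0.5 * z * z)

    return LinkSpec(
        "probit",
        g=lambda p: ndtri(_clip(p)),
        g_inverse=lambda e: ndtr(np.asarray(e, dtype=float)),
        g_prime=g_prime,
    )


def _identity_link() -> LinkSpec:
    return LinkSpec(
        "identity",
        g=lambda p: _clip(p),
        g_inverse=lambda e: np.clip(np.asarray(e, dtype=float), _EPS, 1.0 - _EPS),
        g_prime=lambda p: np.ones_like(_clip(p)),
    )


def _independence_link() -> LinkSpec:
    # g(pi) = -log(1 - pi): additivity on this scale is the independent
    # sufficient causes (locus heterogeneity) model
    return LinkSpec(
        "independence",
        g=lambda p: -np.log1p(-_clip(p)),
        g_inverse=lambda e: np.clip(-np.expm1(-np.asarray(e, dtype=float)), _EPS, 1.0 - _EPS),
        g_prime=lambda p: 1.0 / (1.0 - _clip(p)),
    )


def _power_odds_link(lam: float) -> LinkSpec:
    if lam == 0.0:
        base = _logit_link()
        return LinkSpec("power_odds", base.g, base.g_inverse, base.g_prime, {"lam": 0.0})

    def g(p):
        p = _clip(p)
        # expm1 keeps the Box-Cox transform stable down to lam ~ 1e-300
        return np.expm1(lam * (np.log(p) - np.log1p(-p))) / lam

    def g_inverse(e):
        u = lam * np.asarray(e, dtype=float)
        u = np.maximum(u, _EPS - 1.0)  # keep 1 + lam*eta positive
        return expit(np.log1p(u) / lam)

    def g_prime(p):
        p = _clip(p)
        return (p / (1.0 - p)) ** (lam - 1.0) / (1.0 - p) ** 2

    return LinkSpec("power_odds", g, g_inverse, g_prime, {"lam": float(lam)})


_FACTORIES = {
    "logit": _logit_link,
    "log": _log_link,
    "probit": _probit_link,
    "identity": _identity_link,
    "independence": _independence_link,
}

LINK_NAMES = tuple(_FACTORIES) + ("power_odds",)


def make_link(name: str, lam: float | None = None) -> LinkSpec:
    """Build a built-in link by name.

    Parameters
    ----------
    name : str
        One of ``logit, log, probit, identity, independence, power_odds``.
    lam : float, optional
        Power-odds exponent; required for (and only for) ``power_odds``.
        ``lam = 0`` gives the logit link exactly (Box-Cox limit).
    """
    if name == "power_odds":
        if lam is None:
            raise ValueError("power_odds link requires the exponent lam")
        return _power_odds_link(float(lam))
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(f"unknown link {name!r}; choose from {LINK_NAMES}") from None
    if lam is not None:
        raise ValueError(f"link {name!r} takes no parameter")
    return factory()


def parse_link(spec: str) -> LinkSpec:
    """Parse a config/CLI link string such as ``"probit"`` or ``"power_odds:0.25"``."""
    if ":" in spec:
        name, _, val = spec.partition(":")
        return make_link(name, float(val))
    return make_link(spec)


def _check_prob(x, what):
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError(f"{what} must lie strictly inside (0, 1)")
    return x


def cc_transform(mu, K):
    """Back-transform a case-control probability to the population risk.

    The case-control sample shifts every subject's odds of being a case by
    the sampling ratio K, whatever the population link, so

        logit(pi) = logit(mu) - log K.

    K = 1 is the identity.
    """
    mu = _check_prob(mu, "case-control probability mu")
    K = float(K)
    if K <= 0:
        raise ValueError("sampling ratio K must be positive")
    return expit(_logit(mu) - np.log(K))


def weight(link: LinkSpec, pi):
    """Stratum weight W(pi) = 1 / (g'(pi) pi (1 - pi)) at a population risk.

    Unnormalized: only ratios of weights matter to the tests.
    """
    pi = _check_prob(pi, "population risk pi")
    pi = _clip(pi)
    return 1.0 / (link.g_prime(pi) * pi * (1.0 - pi))


def cc_weight(link: LinkSpec, K, mu):
    """Stratum weight expressed through the study case probability ``mu``.

    Equals ``weight(link, cc_transform(mu, K))`` exactly.  For power-odds
    links the result is ``K**lam * (mu/(1-mu))**(-lam)`` — a pure power of
    the stratum case:control odds times a constant in K, so relative weights
    do not require K at all.
    """
    return weight(link, cc_transform(mu, K))


def powerodds_lambda_matching(link: LinkSpec | None = None,
                              grid: np.ndarray | None = None) -> float:
    """Power-odds exponent whose link is most nearly an affine function of ``link``.

    For each candidate lam the power-odds predictor g_lam(pi) is regressed
    linearly on the target predictor g(pi) over a grid of risks, and the lam
    minimizing the residual sum of squares (relative to the total sum of
    squares) is returned.  Default target is the probit link on
    pi in [0.001, 0.5], the risk range of interest for stratified
    case-control weighting.
    """
    from scipy.optimize import minimize_scalar

    if link is None:
        link = make_link("probit")
    if grid is None:
        grid = np.linspace(0.001, 0.5, 200)
    target = link.g(grid)
    target = target - target.mean()

    def badness(lam):
        y = make_link("power_odds", lam).g(grid)
        y = y - y.mean()
        # residual SS of best affine fit of y on target, scale-free
        denom = float(y @ y)
        if denom == 0.0:
            return 1.0
        slope = float(y @ target) / float(target @ target)
        resid = y - slope * target
        return float(resid @ resid) / denom

    res = minimize_scalar(badness, bounds=(-1.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)
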