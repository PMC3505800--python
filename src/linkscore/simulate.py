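"""Seeded generators for stratified case-control studies and sibling pairs.

The case-control generator computes the exact joint probabilities of
(stratum, genotype) among cases and among controls under the specified risk
model, then draws the study by multinomial sampling to the design's case and
control counts.  This makes small-effect power studies cheap (no cohort
rejection sampling) and keeps the generative model exactly the one the
power calculations in :mod:`linkscore.power` describe: Hardy-Weinberg
genotype independent of stratum in the population, effect constant across
strata on the scale of the chosen link.

The sibling-pair generators draw the latent structure each prediction model
assumes — bivariate normal scores with correlation 1/2 (log-link and
quadratic-log), shared/unshared Poisson variant counts with means mu/2
(independent sufficient causes), bivariate normal liabilities with
correlation H/2 or score-liability correlation sqrt(H) (probit) — and
return per-subject (score, affected) records plus empirical prevalence and
recurrence summaries with delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .assoc import CaseControlData
from .links import LinkSpec
from .power import PopulationScenario, SamplingDesign, cc_composition
from .prediction import ISCModel

__all__ = [
    "SimulationSpec",
    "simulate_cc_study",
    "SibPairResult",
    "simulate_sib_pairs_loglink",
    "simulate_sib_pairs_quadlog",
    "simulate_sib_pairs_isc",
    "simulate_sib_pairs_probit",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Complete recipe for one stratified case-control dataset."""

    scenario: PopulationScenario
    link: LinkSpec
    beta: float
    maf: float = 0.5
    design: SamplingDesign = SamplingDesign(1.0, 2000)
    seed: int = 0


def _genotype_probs(maf: float) -> np.ndarray:
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie in (0, 1)")
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])


def cell_probabilities(spec: SimulationSpec):
    """Exact (stratum, genotype) probabilities among cases and among controls.

    Stratum intercepts are solved so the risk at the mean genotype dose
    equals the stratum's nominal risk; a risk outside (0, 1) at any
    attainable genotype is a specification error.
    """
    sc, link = spec.scenario, spec.link
    q = _genotype_probs(spec.maf)
    xs = np.array([0.0, 1.0, 2.0])
    xbar = 2.0 * spec.maf
    eta0 = link.g(sc.pi)
    eta = eta0[:, None] + spec.beta * (xs[None, :] - xbar)
    risk = link.g_inverse(eta)
    # a clipped inverse maps out-of-range predictors to the boundary; detect
    # that by checking the round trip back to the predictor scale
    ok = (np.isfinite(risk) & (risk > 0.0) & (risk < 1.0)
          & (np.abs(link.g(risk) - eta) <= 1e-6 * np.maximum(1.0, np.abs(eta))))
    if not ok.all():
        raise ValueError("risk model leaves (0, 1) for an attainable genotype")
    joint = sc.f[:, None] * q[None, :]
    p_case = joint * risk
    p_ctrl = joint * (1.0 - risk)
    return p_case / p_case.sum(), p_ctrl / p_ctrl.sum(), risk


def simulate_cc_study(spec: SimulationSpec) -> CaseControlData:
    """Draw one case-control study; identical spec (incl. seed) gives identical data."""
    rng = np.random.default_rng(spec.seed)
    p_case, p_ctrl, _ = cell_probabilities(spec)
    N = int(spec.design.n_total)
    n_case = int(round(N * spec.design.case_fraction))
    n_ctrl = N - n_case
    k = p_case.size
    cc = rng.multinomial(n_case, p_case.ravel())
    c0 = rng.multinomial(n_ctrl, p_ctrl.ravel())
    cells = np.arange(k)
    z = np.concatenate([np.repeat(cells // 3, cc), np.repeat(cells // 3, c0)])
    x = np.concatenate([np.repeat(cells % 3, cc), np.repeat(cells % 3, c0)]).astype(float)
    y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
    return CaseControlData(y=y, z=z, x=x)


@dataclass
class SibPairResult:
    """Empirical summaries from simulated sibling pairs.

    ``lambda_s_hat = p11 / (p1 p2)`` with a delta-method standard error on
    the log scale; ``scores``/``affected`` are the records of sib 1, usable
    for empirical ROC/AUC.
    """

    n_pairs: int
    p_hat: float
    p_se: float
    lambda_s_hat: float
    lambda_s_se: float
    scores: np.ndarray
    affected: np.ndarray
    capped_fraction: float = 0.0

    @property
    def auc_hat(self) -> float:
        """Empirical AUC (rank statistic) of score vs affected for sib 1."""
        from scipy.stats import rankdata

        pos = self.affected.astype(bool)
        n1, n0 = pos.sum(), (~pos).sum()
        if n1 == 0 or n0 == 0:
            return float("nan")
        r = rankdata(self.scores)
        return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _summarize(y1, y2, scores, capped=0.0) -> SibPairResult:
    n = len(y1)
    p11 = max(np.mean(y1 * y2), 1e-300)
    p1 = max(np.mean(y1), 1e-300)
    p2 = max(np.mean(y2), 1e-300)
    lam = p11 / (p1 * p2)
    # delta method for log lambda on the (p11, p10, p01) multinomial
    p10, p01 = p1 - p11, p2 - p11
    g = np.array([1.0 / p11 - 1.0 / p1 - 1.0 / p2, -1.0 / p1, -1.0 / p2])
    pv = np.array([p11, p10, p01])
    cov = (np.diag(pv) - np.outer(pv, pv)) / n
    var_log = float(g @ cov @ g)
    p_all = 0.5 * (p1 + p2)
    return SibPairResult(
        n_pairs=n,
        p_hat=float(p_all),
        p_se=float(np.sqrt(p_all * (1 - p_all) / (2 * n))),
        lambda_s_hat=float(lam),
        lambda_s_se=float(lam * np.sqrt(max(var_log, 0.0))),
        scores=scores,
        affected=y1,
        capped_fraction=capped,
    )


def _bvn_pairs(rng, n_pairs, rho):
    z = rng.standard_normal((n_pairs, 2))
    x1 = z[:, 0]
    x2 = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    return x1, x2


def simulate_sib_pairs_loglink(alpha: float, P: float, n_pairs: int,
                               seed: int = 0) -> SibPairResult:
    """Sibling pairs under the multiplicative model; risks above 1 are capped
    (the capped population fraction is reported)."""
    rng = np.random.default_rng(seed)
    x1, x2 = _bvn_pairs(rng, n_pairs, 0.5)
    c0 = np.log(P) - 0.5 * alpha * alpha
    r1 = np.exp(c0 + alpha * x1)
    r2 = np.exp(c0 + alpha * x2)
    capped = float(np.mean(r1 > 1.0))
    r1, r2 = np.minimum(r1, 1.0), np.minimum(r2, 1.0)
    y1 = (rng.random(n_pairs) < r1).astype(float)
    y2 = (rng.random(n_pairs) < r2).astype(float)
    return _summarize(y1, y2, x1, capped)


def simulate_sib_pairs_quadlog(c1: float, c2: float, P: float, n_pairs: int,
                               seed: int = 0) -> SibPairResult:
    rng = np.random.default_rng(seed)
    from .prediction import _quad_norm_const

    x1, x2 = _bvn_pairs(rng, n_pairs, 0.5)
    c0 = np.log(P) - np.log(_quad_norm_const(c1, c2))
    r1 = np.exp(c0 + c1 * x1 + c2 * x1 * x1)
    r2 = np.exp(c0 + c1 * x2 + c2 * x2 * x2)
    capped = float(np.mean(r1 > 1.0))
    y1 = (rng.random(n_pairs) < np.minimum(r1, 1.0)).astype(float)
    y2 = (rng.random(n_pairs) < np.minimum(r2, 1.0)).astype(float)
    return _summarize(y1, y2, x1, capped)


def simulate_sib_pairs_isc(model: ISCModel, n_pairs: int, seed: int = 0) -> SibPairResult:
    """Sibling pairs under the independent sufficient causes model:
    shared and unshared variant counts are independent Poisson(mu/2)."""
    rng = np.random.default_rng(seed)
    shared = rng.poisson(model.mu / 2.0, n_pairs)
    u1 = rng.poisson(model.mu / 2.0, n_pairs)
    u2 = rng.poisson(model.mu / 2.0, n_pairs)
    x1, x2 = shared + u1, shared + u2
    y1 = (rng.random(n_pairs) < model.risk(x1)).astype(float)
    y2 = (rng.random(n_pairs) < model.risk(x2)).astype(float)
    return _summarize(y1, y2, x1.astype(float))


def simulate_sib_pairs_probit(H: float, P: float, n_pairs: int,
                              seed: int = 0) -> SibPairResult:
    """Sibling pairs under the liability threshold model.

    Liabilities are bivariate normal with correlation H/2 (for recurrence
    checks); sib 1's genetic score is drawn jointly with its liability at
    correlation sqrt(H), so the returned records support empirical ROC
    checks as well.
    """
    rng = np.random.default_rng(seed)
    T = ndtri(1.0 - P)
    rho_l = H / 2.0
    z = rng.standard_normal((n_pairs, 3))
    l1 = z[:, 0]
    l2 = rho_l * z[:, 0] + np.sqrt(1.0 - rho_l * rho_l) * z[:, 1]
    rg = np.sqrt(H)
    g1 = rg * l1 + np.sqrt(max(0.0, 1.0 - H)) * z[:, 2]
    y1 = (l1 > T).astype(float)
    y2 = (l2 > T).astype(float)
    return _summarize(y1, y2, g1)
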