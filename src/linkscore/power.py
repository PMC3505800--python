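"""Asymptotic power of weighted trend tests under link misspecification.

The population falls into discrete risk strata; a case-control study samples
cases and non-cases with a fixed ratio, which both redistributes the study
sample across strata (high-risk strata supply most cases) and induces,
within the sample, an association between stratum and any genotype that
carries risk — even though genotype and stratum are independent in the
population.

For a small genotype effect ``beta`` on the scale of the true link, additive
genotype dose under Hardy-Weinberg proportions, the 1-df chi-squared built
on the weighted marginal statistic ``U = sum_i (x_i - xbar)(ytil_i -
ytilbar)`` (``ytil = w_z y``) has non-centrality

    NCP = N beta^2 Var(x) m(w)^2 / var_til(w),

    m(w)       = sum_z a_z w_z w*_z mu_z (1 - pi_z)
                 - (sum_z a_z w*_z (mu_z - pi_z)) (sum_z a_z w_z mu_z)
    var_til(w) = sum_z a_z w_z^2 mu_z - (sum_z a_z w_z mu_z)^2

where ``a_z`` is the stratum's share of the study sample, ``mu_z`` its case
fraction, ``pi_z`` its population risk, ``w*_z = W_true(pi_z)`` the weight
function of the true link, and ``Var(x) = 2 maf (1 - maf)``.  The second
term of ``m`` is the between-stratum covariance contribution from sampling-
induced genotype-stratum association; the variance is the whole-sample
permutation variance of the reweighted indicator and likewise retains its
between-stratum component.  Both pieces matter: dropping them gives the
purely within-stratum (stratified-test) non-centrality

    NCP_strat = N beta^2 Var(x) (sum_z a_z w_z w*_z mu_z (1-mu_z))^2
                / sum_z a_z w_z^2 mu_z (1 - mu_z).

Efficiency of an analysis weighting ``w`` is the ratio of its NCP to the NCP
with the correctly specified weights ``w*``; it is free of ``beta``, ``N``
and the genotype variance, and invariant to rescaling ``w``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .assoc import WeightScheme
from .links import LinkSpec, weight

__all__ = [
    "PopulationScenario",
    "SamplingDesign",
    "cc_composition",
    "optimal_weights",
    "ncp",
    "efficiency",
    "efficiency_curve",
    "load_scenario",
    "bundled_scenario",
]


@dataclass(frozen=True)
class PopulationScenario:
    """Stratum population fractions and risks."""

    fractions: tuple
    risks: tuple

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        r = np.asarray(self.risks, dtype=float)
        if f.shape != r.shape or f.ndim != 1 or f.size == 0:
            raise ValueError("fractions and risks must be equal-length 1-d sequences")
        if abs(f.sum() - 1.0) > 1e-8 or (f <= 0).any():
            raise ValueError("stratum fractions must be positive and sum to 1")
        if ((r <= 0) | (r >= 1)).any():
            raise ValueError("stratum risks must lie in (0, 1)")

    @classmethod
    def equal_strata(cls, risks) -> "PopulationScenario":
        risks = tuple(float(r) for r in risks)
        k = len(risks)
        return cls(tuple([1.0 / k] * k), risks)

    @property
    def f(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.risks, dtype=float)


@dataclass(frozen=True)
class SamplingDesign:
    """Case:control ratio and total size of the study sample."""

    case_control_ratio: float = 1.0
    n_total: float = 1.0

    def __post_init__(self):
        if self.case_control_ratio <= 0 or self.n_total <= 0:
            raise ValueError("ratio and sample size must be positive")

    @property
    def case_fraction(self) -> float:
        return self.case_control_ratio / (1.0 + self.case_control_ratio)


def cc_composition(scenario: PopulationScenario, design: SamplingDesign):
    """Per-stratum study share ``a_z`` and case probability ``mu_z``.

    Cases arise from stratum z with probability proportional to
    ``f_z pi_z``, controls to ``f_z (1 - pi_z)``; mixing with the design's
    case fraction gives each stratum's share of the sample and its internal
    case fraction.
    """
    f, pi = scenario.f, scenario.pi
    case_src = f * pi / np.sum(f * pi)
    ctrl_src = f * (1.0 - pi) / np.sum(f * (1.0 - pi))
    q = design.case_fraction
    a = q * case_src + (1.0 - q) * ctrl_src
    mu = q * case_src / a
    return a, mu


def optimal_weights(scenario: PopulationScenario, design: SamplingDesign,
                    true_link: LinkSpec) -> WeightScheme:
    """Efficient stratum weights under the given true link: ``w*_z = W(pi_z)``."""
    w = weight(true_link, scenario.pi)
    return WeightScheme({i: float(wi) for i, wi in enumerate(w)},
                        provenance=f"optimal:{true_link.label}")


def _weight_array(scenario: PopulationScenario, weights: WeightScheme) -> np.ndarray:
    return weights.vector(np.arange(len(scenario.risks)))


def ncp(scenario: PopulationScenario, design: SamplingDesign,
        true_link: LinkSpec, beta: float, maf: float = 0.5,
        N: float | None = None, analysis_weights: WeightScheme | None = None,
        mode: str = "marginal") -> float:
    """Local-alternative non-centrality of the 1-df weighted trend test.

    ``beta`` is the per-dose effect on the true-link scale, constant across
    strata; the genotype is diallelic, Hardy-Weinberg, additively coded, so
    ``Var(x) = 2 maf (1 - maf)``.  ``mode='marginal'`` is the pooled
    reweighted-indicator test (the design of interest when genotype and
    stratum are independent in the population); ``mode='stratified'`` the
    within-stratum test.
    """
    if mode not in ("marginal", "stratified"):
        raise ValueError("mode must be 'marginal' or 'stratified'")
    if N is None:
        N = design.n_total
    a, mu = cc_composition(scenario, design)
    pi = scenario.pi
    wstar = weight(true_link, pi)
    w = wstar if analysis_weights is None else _weight_array(scenario, analysis_weights)
    varx = 2.0 * maf * (1.0 - maf)
    if mode == "stratified":
        info = a * mu * (1.0 - mu)
        m = float(np.sum(info * w * wstar))
        v = float(np.sum(info * w * w))
    else:
        m = float(np.sum(a * w * wstar * mu * (1.0 - pi))
                  - np.sum(a * wstar * (mu - pi)) * np.sum(a * w * mu))
        v = float(np.sum(a * w * w * mu) - np.sum(a * w * mu) ** 2)
    if v <= 0.0:
        return 0.0
    return float(N) * beta * beta * varx * m * m / v


def efficiency(scenario: PopulationScenario, design: SamplingDesign,
               true_link: LinkSpec, analysis_weights: WeightScheme,
               mode: str = "marginal") -> float:
    """Relative efficiency of an analysis weighting under a given truth.

    Ratio of the test's non-centrality with ``analysis_weights`` to its
    value with the correctly specified weights ``W_true(pi_z)``; free of the
    effect size, sample size and allele frequency, and invariant to global
    rescaling of the weights.
    """
    num = ncp(scenario, design, true_link, beta=1.0, N=1.0,
              analysis_weights=analysis_weights, mode=mode)
    den = ncp(scenario, design, true_link, beta=1.0, N=1.0,
              analysis_weights=None, mode=mode)
    return num / den


def efficiency_curve(scenario: PopulationScenario, design: SamplingDesign,
                     lambdas, panel: str = "generate",
                     mode: str = "marginal") -> dict:
    """Efficiency along the power-odds family.

    ``panel='generate'``: data generated at each exponent ``lam``, analysed
    with unit weights (``lam = 0``, the standard Cochran-Armitage test).
    ``panel='analyse'``: data generated under the logistic model, analysed
    with power-odds weights at each ``lam``.  Either way the reference is
    the correctly specified weighting, so the curve equals 1 exactly at
    ``lam = 0``.
    """
    from .links import make_link

    if panel not in ("generate", "analyse"):
        raise ValueError("panel must be 'generate' or 'analyse'")
    lambdas = np.asarray(lambdas, dtype=float)
    strata = range(len(scenario.risks))
    unit = WeightScheme.unit(strata)
    effs = []
    for lam in lambdas:
        po = make_link("power_odds", float(lam))
        if panel == "generate":
            effs.append(efficiency(scenario, design, po, unit, mode=mode))
        else:
            w = WeightScheme({i: float(v) for i, v in
                              zip(strata, weight(po, scenario.pi))},
                             provenance=po.label)
            effs.append(efficiency(scenario, design, make_link("logit"), w, mode=mode))
    return {"lambda": lambdas.tolist(), "efficiency": effs, "panel": panel}


def load_scenario(path) -> PopulationScenario:
    """Read a scenario JSON file: ``{"fractions": [...], "risks": [...]}``."""
    with open(path) as fh:
        obj = json.load(fh)
    if "fractions" not in obj or "risks" not in obj:
        raise ValueError("scenario JSON needs 'fractions' and 'risks'")
    return PopulationScenario(tuple(obj["fractions"]), tuple(obj["risks"]))


def bundled_scenario(name: str) -> PopulationScenario:
    """Load one of the packaged stratification scenarios (``scenario1``/``scenario2``)."""
    from importlib.resources import files

    path = files("linkscore") / "scenarios" / f"{name}.json"
    obj = json.loads(path.read_text())
    return PopulationScenario(tuple(obj["fractions"]), tuple(obj["risks"]))
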