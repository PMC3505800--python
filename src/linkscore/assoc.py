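"""Weighted stratified and weighted marginal score tests for case-control data.

Both tests start from the score statistic of a binomial GLM for disease
status on a genotype dose, evaluated under the null.  With discrete risk
strata ``z`` and stratum weights ``w_z`` (from :mod:`linkscore.links`):

* **stratified** —  ``U = sum_z w_z sum_{i in z} (x_i - xbar_z)(y_i - ybar_z)``;
  the null distribution conditions on both margins within each stratum, so
  the variance is the within-stratum permutation variance
  ``V = sum_z w_z^2 n_z^2/(n_z - 1) S2(x_z) S2(y_z)``
  (``S2`` the divide-by-n sample variance).  With unit weights and one
  stratum this is the classic Cochran-Armitage trend test; with unit weights
  and several strata, Mantel's extension.

* **marginal** — valid when genotype and stratum are independent in the
  population; replace the 0/1 case indicator by ``0`` (controls) /
  ``w_z`` (cases) and run the unstratified test on the pooled sample:
  ``U = sum_i (x_i - xbar)(ytil_i - ytilbar)``,
  ``V = N^2/(N-1) S2(x) S2(ytil)``, with the null generated by permuting
  ``x`` against ``ytil`` over the whole sample.  With unit weights this is
  exactly the Cochran-Armitage test ignoring the stratification.

Either statistic is referred to chi-squared on 1 df as ``U^2/V``; a 2-df
variant codes the genotype as two indicator columns and uses the permutation
covariance matrix.  Exact permutation p-values use the same permutation
schemes.  All tests are invariant to a global rescaling of the weights and
to affine recoding of the genotype dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .links import LinkSpec, cc_weight

__all__ = [
    "CaseControlData",
    "WeightScheme",
    "TestResult",
    "stratified_test",
    "marginal_test",
    "two_df_test",
    "permutation_pvalue",
]


@dataclass
class CaseControlData:
    """Per-subject phenotype, stratum label and genotype score(s).

    ``x`` is a numeric genotype dose (conventionally 0/1/2 with the
    heterozygote at the midpoint; any affine recoding gives the same tests).
    ``x2`` optionally holds the second indicator column for the 2-df test,
    in which case ``x`` is the first indicator.
    """

    y: np.ndarray
    z: np.ndarray
    x: np.ndarray
    x2: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z)
        if self.x2 is not None:
            self.x2 = np.asarray(self.x2, dtype=float)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotype y must be coded 0/1")
        self.y = self.y.astype(float)
        n = len(self.y)
        if len(self.x) != n or len(self.z) != n or (self.x2 is not None and len(self.x2) != n):
            raise ValueError("y, z, x (and x2) must have equal length")
        if n == 0:
            raise ValueError("empty dataset")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def strata(self) -> np.ndarray:
        return np.unique(self.z)

    def stratum_case_fractions(self) -> dict:
        """Observed case fraction per stratum (the mu-hat used for weights)."""
        return {s: float(self.y[self.z == s].mean()) for s in self.strata}


@dataclass
class WeightScheme:
    """Positive per-stratum weights plus a provenance tag.

    Weights are used only through their ratios; tests are invariant to a
    global rescaling.
    """

    weights: dict
    provenance: str = "unit"

    def __post_init__(self):
        for s, w in self.weights.items():
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"weight for stratum {s!r} must be positive, got {w}")

    @classmethod
    def unit(cls, strata) -> "WeightScheme":
        return cls({s: 1.0 for s in strata}, provenance="unit")

    @classmethod
    def from_link(cls, link: LinkSpec, K: float, mu_by_stratum: dict) -> "WeightScheme":
        """Weights from stratum case fractions through an assumed link and sampling ratio."""
        w = {s: float(cc_weight(link, K, mu)) for s, mu in mu_by_stratum.items()}
        return cls(w, provenance=f"{link.label}, K={K:g}")

    @classmethod
    def from_data(cls, data: CaseControlData, link: LinkSpec, K: float) -> "WeightScheme":
        """Estimate stratum case fractions from the data, then apply the link."""
        mu = data.stratum_case_fractions()
        bad = [s for s, m in mu.items() if m <= 0.0 or m >= 1.0]
        for s in bad:
            # all-case or all-control stratum: weight is arbitrary, its
            # contribution to the stratified statistic is zero anyway
            mu[s] = 0.5
        scheme = cls.from_link(link, K, mu)
        if bad:
            scheme.provenance += f" ({len(bad)} degenerate strata at unit weight)"
        return scheme

    def vector(self, z: np.ndarray) -> np.ndarray:
        try:
            return np.array([self.weights[s] for s in z], dtype=float)
        except KeyError as e:
            raise ValueError(f"no weight defined for stratum {e.args[0]!r}") from None


@dataclass
class TestResult:
    """Score statistic, permutation variance and p-values for one test."""

    U: np.ndarray | float
    V: np.ndarray | float
    chi2: float
    df: int
    p_asymptotic: float
    mode: str
    weights: str = "unit"
    warnings: list = field(default_factory=list)
    p_permutation: float | None = None
    n_permutations: int | None = None
    permutation_se: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "U": np.asarray(self.U).tolist(),
            "V": np.asarray(self.V).tolist(),
            "chi2": self.chi2,
            "df": self.df,
            "p_asymptotic": self.p_asymptotic,
            "mode": self.mode,
            "weights": self.weights,
            "warnings": list(self.warnings),
        }
        if self.p_permutation is not None:
            out.update(
                p_permutation=self.p_permutation,
                n_permutations=self.n_permutations,
                permutation_se=self.permutation_se,
                seed=self.seed,
            )
        return out


def _biased_var(v: np.ndarray) -> float:
    return float(np.var(v))  # numpy default ddof=0 is the divide-by-n variance


def _stratified_UV(y, z, x, wvec):
    """Weighted within-stratum score and its exact permutation variance."""
    U = 0.0
    V = 0.0
    degenerate = 0
    for s in np.unique(z):
        m = z == s
        n_z = int(m.sum())
        if n_z < 2:
            degenerate += 1
            continue
        xs, ys = x[m], y[m]
        w = wvec[m][0]
        U += w * float((xs - xs.mean()) @ (ys - ys.mean()))
        sx, sy = _biased_var(xs), _biased_var(ys)
        if sx == 0.0 or sy == 0.0:
            degenerate += 1
            continue
        V += w * w * n_z * n_z / (n_z - 1.0) * sx * sy
    return U, V, degenerate


def _marginal_UV(y, z, x, wvec):
    ytil = wvec * y
    n = len(y)
    U = float((x - x.mean()) @ (ytil - ytil.mean()))
    V = n * n / (n - 1.0) * _biased_var(x) * _biased_var(ytil)
    return U, V


def _finalize_1df(U, V, mode, weights, warnings):
    if V <= 0.0:
        warnings = warnings + ["degenerate data: zero permutation variance"]
        return TestResult(U, 0.0, 0.0, 1, 1.0, mode, weights, warnings)
    chi2 = U * U / V
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(U, V, chi2, 1, p, mode, weights, warnings)


def stratified_test(data: CaseControlData, weights: WeightScheme) -> TestResult:
    """Weighted stratified trend test (Mantel extension with stratum weights).

    Strata with a single subject, or with constant genotype or phenotype,
    contribute zero to both the score and its variance; they are counted in
    ``warnings``.
    """
    wvec = weights.vector(data.z)
    U, V, degenerate = _stratified_UV(data.y, data.z, data.x, wvec)
    warn = [f"{degenerate} strata contributed nothing (constant x or y, or n=1)"] if degenerate else []
    return _finalize_1df(U, V, "stratified", weights.provenance, warn)


def marginal_test(data: CaseControlData, weights: WeightScheme) -> TestResult:
    """Weighted marginal (unstratified) test, assuming genotype independent of stratum.

    The case indicator is replaced by 0 (controls) / ``w_z`` (cases) and the
    ordinary trend test run on the pooled sample.
    """
    wvec = weights.vector(data.z)
    U, V = _marginal_UV(data.y, data.z, data.x, wvec)
    return _finalize_1df(U, V, "marginal", weights.provenance, [])


def _two_df_UV(y, z, x1, x2, wvec, mode):
    X = np.column_stack([x1, x2])
    if mode == "stratified":
        U = np.zeros(2)
        V = np.zeros((2, 2))
        for s in np.unique(z):
            m = z == s
            n_z = int(m.sum())
            if n_z < 2:
                continue
            Xs = X[m] - X[m].mean(axis=0)
            ys = y[m] - y[m].mean()
            w = wvec[m][0]
            U += w * Xs.T @ ys
            V += w * w * (Xs.T @ Xs) * float(ys @ ys) / (n_z - 1.0)
        return U, V
    ytil = wvec * y
    Xc = X - X.mean(axis=0)
    yc = ytil - ytil.mean()
    U = Xc.T @ yc
    V = (Xc.T @ Xc) * float(yc @ yc) / (len(y) - 1.0)
    return U, V


def two_df_test(data: CaseControlData, weights: WeightScheme,
                mode: str = "stratified") -> TestResult:
    """2-df genotype test from two indicator codings.

    The quadratic form ``U' V^- U`` uses a generalized inverse, with the
    degrees of freedom reduced to the rank of the permutation covariance
    matrix; rank 0 returns p = 1 with a warning.
    """
    if data.x2 is None:
        raise ValueError("two_df_test requires a second genotype column x2")
    if mode not in ("stratified", "marginal"):
        raise ValueError("mode must be 'stratified' or 'marginal'")
    wvec = weights.vector(data.z)
    U, V = _two_df_UV(data.y, data.z, data.x, data.x2, wvec, mode)
    rank = int(np.linalg.matrix_rank(V, tol=1e-10 * max(1.0, float(np.abs(V).max()))))
    if rank == 0:
        return TestResult(U, V, 0.0, 0, 1.0, mode, weights.provenance,
                          ["rank-0 covariance: no genotype variation"])
    Vinv = np.linalg.pinv(V)
    chi2 = float(U @ Vinv @ U)
    p = float(stats.chi2.sf(chi2, df=rank))
    warn = [] if rank == 2 else [f"covariance rank {rank}: df reduced"]
    return TestResult(U, V, chi2, rank, p, mode, weights.provenance, warn)


def permutation_pvalue(data: CaseControlData, weights: WeightScheme,
                       mode: str = "stratified", n_perm: int = 1000,
                       seed: int = 0) -> TestResult:
    """Exact (Monte-Carlo) two-sided permutation p-value for the 1-df test.

    Stratified mode permutes the genotype within each stratum, conditioning
    on both margins of every stratum table; marginal mode permutes the
    genotype against the reweighted indicator over the whole sample.
    ``p = (1 + #{|U*| >= |U|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if mode not in ("stratified", "marginal"):
        raise ValueError("mode must be 'stratified' or 'marginal'")
    rng = np.random.default_rng(seed)
    wvec = weights.vector(data.z)
    y, z, x = data.y, data.z, data.x

    if mode == "stratified":
        base = stratified_test(data, weights)
        masks = [z == s for s in np.unique(z)]

        def stat(xp):
            return _stratified_UV(y, z, xp, wvec)[0]

        def permute(xp):
            for m in masks:
                xp[m] = rng.permutation(xp[m])
            return xp
    else:
        base = marginal_test(data, weights)

        def stat(xp):
            return _marginal_UV(y, z, xp, wvec)[0]

        def permute(xp):
            return rng.permutation(xp)

    U_obs = abs(float(np.asarray(base.U)))
    hits = 0
    xp = x.copy()
    for _ in range(n_perm):
        xp = permute(xp)
        if abs(stat(xp)) >= U_obs - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    base.p_permutation = p
    base.n_permutations = n_perm
    base.permutation_se = float(np.sqrt(p * (1.0 - p) / n_perm))
    base.seed = seed
    return base
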