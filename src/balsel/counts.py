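"""Core statistics for the shared-vs-private polymorphism test of balancing selection.

The central object is a 2x2 contingency table of polymorphism counts,
cross-classifying sites by functional class (nonsynonymous vs synonymous) and
by whether they segregate in both of two populations (shared) or in exactly
one (private).  Writing the four cells S_N, S_S, R_N, R_S, the test statistic

    Z = (S_N / S_S) / (R_N / R_S)

equals 1 when all nonsynonymous mutations are neutral or strongly deleterious,
and exceeds 1 when balancing selection maintains nonsynonymous polymorphisms
across the population split.  Under a simple model in which synonymous
mutations are neutral and nonsynonymous mutations are neutral, strongly
deleterious, or balanced, the proportion of shared nonsynonymous polymorphisms
directly maintained by balancing selection is

    alpha_b = 1 - 1/Z = b / S_N,

where b is the number of balanced polymorphisms, so b can be estimated as
alpha_b * S_N.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PolymorphismCounts",
    "ExpectedModelParams",
    "AlphaEstimate",
    "TestResult",
    "BootstrapResult",
    "UndefinedStatisticError",
    "compute_z",
    "compute_alpha_b",
    "estimate_b",
    "expected_counts",
    "chi2_test",
    "fisher_exact_one_tailed",
    "bootstrap_ci",
]


class UndefinedStatisticError(ValueError):
    """Raised when a ratio statistic is undefined because a count cell is zero."""


@dataclass(frozen=True)
class PolymorphismCounts:
    """The 2x2 table of shared/private x nonsynonymous/synonymous polymorphism counts.

    Counts are non-negative; real values are permitted because expectation
    tables and bootstrap-weighted sums are also carried in this container.
    """

    s_n: float
    s_s: float
    r_n: float
    r_s: float

    def __post_init__(self) -> None:
        for name in ("s_n", "s_s", "r_n", "r_s"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"count {name} must be finite and non-negative, got {v}")

    def __add__(self, other: "PolymorphismCounts") -> "PolymorphismCounts":
        return PolymorphismCounts(
            self.s_n + other.s_n,
            self.s_s + other.s_s,
            self.r_n + other.r_n,
            self.r_s + other.r_s,
        )

    def as_table(self) -> np.ndarray:
        """Return the table as [[s_n, s_s], [r_n, r_s]]."""
        return np.array([[self.s_n, self.s_s], [self.r_n, self.r_s]], dtype=float)

    @property
    def total(self) -> float:
        return self.s_n + self.s_s + self.r_n + self.r_s


@dataclass(frozen=True)
class ExpectedModelParams:
    """Parameters of the analytic model for expected shared/private counts.

    theta
        Scaled mutation rate per site, 4*N_e*u.  May be given directly or via
        ``n_e`` and ``u``.
    rho
        Proportion of polymorphisms that are private to the population.
    watterson_w
        Watterson's coefficient, treated as a supplied dimensionless factor
        (it cancels in alpha_b).
    f
        Proportion of nonsynonymous mutations that are neutral.
    b
        Number of balanced nonsynonymous polymorphisms.
    x
        Number of neutral mutations maintained in linkage disequilibrium per
        balanced polymorphism.
    """

    theta: float
    rho: float
    watterson_w: float = 1.0
    f: float = 1.0
    b: float = 0.0
    x: float = 0.0
    n_e: float | None = None
    u: float | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.watterson_w < 0 or self.b < 0 or self.x < 0:
            raise ValueError("watterson_w, b, and x must be non-negative")
        if self.n_e is not None and self.u is not None:
            expect = 4.0 * self.n_e * self.u
            if not math.isclose(expect, self.theta, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"theta={self.theta} inconsistent with 4*n_e*u={expect}"
                )

    @classmethod
    def from_population(
        cls,
        n_e: float,
        u: float,
        rho: float,
        watterson_w: float = 1.0,
        f: float = 1.0,
        b: float = 0.0,
        x: float = 0.0,
    ) -> "ExpectedModelParams":
        return cls(4.0 * n_e * u, rho, watterson_w, f, b, x, n_e=n_e, u=u)


@dataclass(frozen=True)
class AlphaEstimate:
    """Point and interval estimate of the balanced fraction and number.

    ``alpha_b`` may be negative (Z < 1); it is reported as-is.
    """

    alpha_b: float
    b_hat: float
    ci_low: float | None = None
    ci_high: float | None = None
    b_ci_low: float | None = None
    b_ci_high: float | None = None

    @property
    def b_hat_rounded(self) -> int:
        return round(self.b_hat)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile-bootstrap summary for a statistic of the pooled table."""

    statistic: str
    point: float
    ci_low: float
    ci_high: float
    std_error: float
    level: float
    n_replicates: int
    n_dropped: int
    replicate_values: np.ndarray


def _require_positive(counts: PolymorphismCounts, cells: Sequence[str]) -> None:
    for name in cells:
        if getattr(counts, name) <= 0:
            raise UndefinedStatisticError(
                f"statistic undefined: cell {name} is zero in {counts}"
            )


def compute_z(counts: PolymorphismCounts) -> float:
    """Ratio of nonsynonymous:synonymous among shared over private polymorphisms.

    Z = (S_N/S_S)/(R_N/R_S); Z > 1 is the signature of balancing selection.
    """
    _require_positive(counts, ("s_s", "r_n", "r_s"))
    return (counts.s_n / counts.s_s) / (counts.r_n / counts.r_s)


def compute_alpha_b(counts: PolymorphismCounts) -> float:
    """Proportion of shared nonsynonymous polymorphisms maintained by balancing selection.

    alpha_b = 1 - (S_S*R_N)/(S_N*R_S), equal to 1 - 1/Z wherever both are
    defined.  Negative values (Z < 1) are returned untruncated.
    """
    _require_positive(counts, ("s_n", "r_s"))
    return 1.0 - (counts.s_s * counts.r_n) / (counts.s_n * counts.r_s)


def estimate_b(alpha_b: float, s_n: float) -> float:
    """Number of balanced polymorphisms, b = alpha_b * S_N (real-valued)."""
    if s_n < 0:
        raise ValueError("s_n must be non-negative")
    return alpha_b * s_n


def expected_counts(params: ExpectedModelParams) -> PolymorphismCounts:
    """Expected shared/private counts under the analytic model.

    R_S = theta*rho*W
    R_N = theta*rho*W*f
    S_S = theta*(1-rho)*W + b*x
    S_N = theta*(1-rho)*W*f + b + b*x*f

    Private counts come only from neutral mutation; shared counts additionally
    contain the b balanced polymorphisms and the x neutral variants each of
    them maintains in linkage disequilibrium.
    """
    base = params.theta * params.watterson_w
    r_s = base * params.rho
    r_n = r_s * params.f
    s_s = base * (1.0 - params.rho) + params.b * params.x
    s_n = base * (1.0 - params.rho) * params.f + params.b + params.b * params.x * params.f
    return PolymorphismCounts(s_n, s_s, r_n, r_s)


def chi2_test(counts: PolymorphismCounts, correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on the 2x2 table, 1 df.

    No continuity correction by default; set ``correction=True`` for Yates.
    """
    table = counts.as_table()
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise UndefinedStatisticError(f"degenerate table (zero marginal): {counts}")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="chi2")


def fisher_exact_one_tailed(counts: PolymorphismCounts) -> TestResult:
    """One-tailed Fisher's exact test for an excess of shared nonsynonymous sites.

    Tests the alternative in the direction Z > 1 (odds ratio of the table
    [[S_N, S_S], [R_N, R_S]] greater than 1).  Degenerate tables return p = 1.
    """
    table = np.asarray(counts.as_table(), dtype=np.int64)
    if not np.allclose(table, counts.as_table()):
        raise ValueError("Fisher's exact test requires integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return TestResult(statistic=float("nan"), p_value=1.0, method="fisher_one_tailed")
    odds, p = sps.fisher_exact(table, alternative="greater")
    return TestResult(statistic=float(odds), p_value=float(p), method="fisher_one_tailed")


_STATISTICS = {
    "Z": compute_z,
    "alpha_b": compute_alpha_b,
    "b": lambda c: compute_alpha_b(c) * c.s_n,
}


def _pool(tables: Sequence[PolymorphismCounts]) -> PolymorphismCounts:
    pooled = PolymorphismCounts(0, 0, 0, 0)
    for t in tables:
        pooled = pooled + t
    return pooled


def bootstrap_ci(
    gene_tables: Iterable[PolymorphismCounts],
    statistic: str = "Z",
    replicates: int = 100,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> BootstrapResult:
    """Gene-level bootstrap of a pooled-table statistic.

    Genes are resampled with replacement; the four counts are summed within
    each bootstrap replicate and the statistic recomputed on the summed table.
    The point estimate is the statistic of the un-resampled pooled table; the
    interval is the percentile interval at ``level``.  Replicates on which the
    statistic is undefined (a required cell resampled to zero) are dropped and
    counted in ``n_dropped``.
    """
    tables = list(gene_tables)
    if len(tables) < 2:
        raise ValueError("bootstrap requires at least 2 genes")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    stat_fn = _STATISTICS[statistic]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    point = stat_fn(_pool(tables))

    arr = np.array([[t.s_n, t.s_s, t.r_n, t.r_s] for t in tables], dtype=float)
    n = len(tables)
    values = []
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        s_n, s_s, r_n, r_s = arr[idx].sum(axis=0)
        try:
            values.append(stat_fn(PolymorphismCounts(s_n, s_s, r_n, r_s)))
        except UndefinedStatisticError:
            dropped += 1
    if not values:
        raise UndefinedStatisticError("all bootstrap replicates were undefined")
    vals = np.asarray(values)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    se = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return BootstrapResult(
        statistic=statistic,
        point=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        std_error=se,
        level=level,
        n_replicates=replicates,
        n_dropped=dropped,
        replicate_values=vals,
    )


def z_log_se(counts: PolymorphismCounts) -> float:
    """Delta-method standard error of ln Z from Poisson-count variation.

    var(ln Z) ~ 1/S_N + 1/S_S + 1/R_N + 1/R_S.  Used as the Monte-Carlo
    standard error of pooled-simulation Z values.
    """
    _require_positive(counts, ("s_n", "s_s", "r_n", "r_s"))
    return math.sqrt(
        1.0 / counts.s_n + 1.0 / counts.s_s + 1.0 / counts.r_n + 1.0 / counts.r_s
    )
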