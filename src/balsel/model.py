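"""Model/Results interface for the shared-vs-private balancing-selection test.

``BalancingSelectionModel`` is built from per-gene count tables (or a tidy
DataFrame with columns gene_id, s_n, s_s, r_n, r_s); ``fit`` pools the counts,
computes Z, alpha_b = 1 - 1/Z and b = alpha_b * S_N, derives gene-level
bootstrap confidence intervals, and attaches chi-squared and one-tailed Fisher
significance tests.  The returned ``BalancingSelectionResults`` carries the
estimates and renders a text summary table.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import counts as cs
from .counts import BootstrapResult, PolymorphismCounts, TestResult

__all__ = ["BalancingSelectionModel", "BalancingSelectionResults"]


class BalancingSelectionModel:
    """Test for balancing selection from per-gene shared/private polymorphism counts.

    Parameters
    ----------
    gene_tables
        Per-gene ``PolymorphismCounts``; pooled by summation before any
        statistic is computed (ratio of sums, not mean of ratios).
    gene_ids
        Optional labels, parallel to ``gene_tables``.
    """

    def __init__(
        self,
        gene_tables: Iterable[PolymorphismCounts],
        gene_ids: Sequence[str] | None = None,
    ) -> None:
        self.gene_tables = list(gene_tables)
        if not self.gene_tables:
            raise ValueError("at least one gene table is required")
        if gene_ids is not None and len(gene_ids) != len(self.gene_tables):
            raise ValueError("gene_ids length must match gene_tables")
        self.gene_ids = list(gene_ids) if gene_ids is not None else [
            f"gene{i}" for i in range(len(self.gene_tables))
        ]
        self.pooled = sum(self.gene_tables[1:], start=self.gene_tables[0])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BalancingSelectionModel":
        """Build from a DataFrame with columns gene_id, s_n, s_s, r_n, r_s."""
        required = {"gene_id", "s_n", "s_s", "r_n", "r_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        tables = [
            PolymorphismCounts(row.s_n, row.s_s, row.r_n, row.r_s)
            for row in df.itertuples()
        ]
        return cls(tables, gene_ids=list(df["gene_id"].astype(str)))

    def fit(
        self,
        bootstrap_replicates: int = 100,
        level: float = 0.95,
        seed: int | np.random.Generator | None = None,
    ) -> "BalancingSelectionResults":
        """Pool counts, estimate Z/alpha_b/b with bootstrap CIs, and run the tests.

        Bootstrapping resamples genes with replacement (the unit that captures
        all between-gene variance); with a single gene no interval is formed.
        """
        pooled = self.pooled
        z = cs.compute_z(pooled)
        alpha_b = cs.compute_alpha_b(pooled)
        b_hat = cs.estimate_b(alpha_b, pooled.s_n)
        chi2 = cs.chi2_test(pooled)
        try:
            fisher = cs.fisher_exact_one_tailed(pooled)
        except ValueError:
            fisher = None

        boots: dict[str, BootstrapResult] = {}
        if len(self.gene_tables) >= 2 and bootstrap_replicates >= 1:
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            for stat in ("Z", "alpha_b", "b"):
                boots[stat] = cs.bootstrap_ci(
                    self.gene_tables, stat, bootstrap_replicates, level, rng
                )
        return BalancingSelectionResults(
            model=self,
            pooled=pooled,
            z=z,
            alpha_b=alpha_b,
            b_hat=b_hat,
            chi2=chi2,
            fisher=fisher,
            bootstraps=boots,
            level=level,
        )


@dataclass
class BalancingSelectionResults:
    """Estimates, uncertainties and diagnostics from a fitted balancing-selection test."""

    model: BalancingSelectionModel
    pooled: PolymorphismCounts
    z: float
    alpha_b: float
    b_hat: float
    chi2: TestResult
    fisher: TestResult | None
    bootstraps: dict[str, BootstrapResult] = field(default_factory=dict)
    level: float = 0.95

    @property
    def p_chi2(self) -> float:
        return self.chi2.p_value

    @property
    def p_fisher(self) -> float | None:
        return self.fisher.p_value if self.fisher is not None else None

    @property
    def n_boot_dropped(self) -> int:
        return max((b.n_dropped for b in self.bootstraps.values()), default=0)

    def conf_int(self, statistic: str = "Z") -> tuple[float, float]:
        b = self.bootstraps[statistic]
        return (b.ci_low, b.ci_high)

    def to_frame(self) -> pd.DataFrame:
        """One-row tidy frame of all estimates (the TSV output schema)."""
        row = {
            "s_n": self.pooled.s_n,
            "s_s": self.pooled.s_s,
            "r_n": self.pooled.r_n,
            "r_s": self.pooled.r_s,
            "Z": self.z,
            "alpha_b": self.alpha_b,
            "b": self.b_hat,
            "p_chi2": self.p_chi2,
            "p_fisher": self.p_fisher,
            "n_boot_dropped": self.n_boot_dropped,
        }
        for stat, boot in self.bootstraps.items():
            row[f"{stat}_ci_low"] = boot.ci_low
            row[f"{stat}_ci_high"] = boot.ci_high
            row[f"{stat}_se"] = boot.std_error
        return pd.DataFrame([row])

    def summary(self) -> str:
        """Human-readable summary table."""
        p = self.pooled
        lines = [
            "Balancing selection test (shared vs private polymorphism)",
            "=" * 58,
            f"genes: {len(self.model.gene_tables)}",
            f"pooled counts   S_N={p.s_n:g}  S_S={p.s_s:g}  R_N={p.r_n:g}  R_S={p.r_s:g}",
            "-" * 58,
            f"{'statistic':<10}{'estimate':>12}{'ci_low':>12}{'ci_high':>12}",
        ]
        for stat, value in (("Z", self.z), ("alpha_b", self.alpha_b), ("b", self.b_hat)):
            if stat in self.bootstraps:
                b = self.bootstraps[stat]
                lines.append(f"{stat:<10}{value:>12.4f}{b.ci_low:>12.4f}{b.ci_high:>12.4f}")
            else:
                lines.append(f"{stat:<10}{value:>12.4f}{'':>12}{'':>12}")
        lines.append("-" * 58)
        lines.append(f"chi-squared (1 df, no correction): stat={self.chi2.statistic:.4f}, p={self.chi2.p_value:.4g}")
        if self.fisher is not None:
            lines.append(f"Fisher one-tailed (Z>1): p={self.fisher.p_value:.4g}")
        if self.bootstraps:
            b = next(iter(self.bootstraps.values()))
            lines.append(
                f"bootstrap: {b.n_replicates} gene-level replicates at level {self.level:.0%}, "
                f"{self.n_boot_dropped} undefined replicate(s) dropped"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<BalancingSelectionResults Z={self.z:.4f} alpha_b={self.alpha_b:.4f} "
            f"b={self.b_hat:.1f}>"
        )
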