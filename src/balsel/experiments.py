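"""Monte-Carlo experiment drivers: Z-versus-time curves, demographic
false-positive sweeps, recovery of the balanced fraction, and single-gene power.

All pooled statistics are ratio-of-sums: the four counts are summed across
replicates first and Z computed on the pooled table (the mean of per-replicate
Z is biased for a ratio).  Monte-Carlo standard errors for pooled Z use the
delta-method approximation SE(ln Z) = sqrt(1/S_N + 1/S_S + 1/R_N + 1/R_S).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import PolymorphismCounts, UndefinedStatisticError, compute_alpha_b, compute_z, z_log_se
from .simulate import (
    BalancedPolyConfig,
    BatchResult,
    DFEParams,
    DominanceModel,
    LocusStructure,
    ScenarioConfig,
    run_batch,
)

__all__ = [
    "ZCurve",
    "RecoveryResult",
    "z_curve_experiment",
    "z_curve_from_batch",
    "alpha_recovery_experiment",
    "recovery_from_batches",
    "recovery_frame",
    "single_gene_power_experiment",
    "PowerResult",
]

_N_BINS = 5


def _bin_labels(bin_width: float) -> list[str]:
    n_bins = int(round(0.5 / bin_width))
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    return [f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(edges[:-1], edges[1:])]


@dataclass
class ZCurve:
    """Per-time, per-bin pooled Z summaries over replicates.

    ``frame`` is tidy: one row per (sample time, frequency bin, focal
    population) with the pooled counts, Z (NaN where undefined), its
    delta-method Monte-Carlo standard error, and the replicate count.  Bins
    are the folded-MAF bins plus ``">0.1"`` (pooled) and ``"all"``.
    """

    frame: pd.DataFrame
    n_replicates: int
    manifest: dict = field(default_factory=dict)

    def z(self, time_n: float, bin_label: str, focal: str = "pop1") -> float:
        sel = self.frame[
            (self.frame.time_n == time_n)
            & (self.frame.bin == bin_label)
            & (self.frame.focal == focal)
        ]
        if sel.empty:
            raise KeyError((time_n, bin_label, focal))
        return float(sel.z.iloc[0])


def _rows_for_table(
    t: PolymorphismCounts, time_n: float, bin_label: str, focal: str, n_rep: int
) -> dict:
    try:
        z = compute_z(t)
        se = z * z_log_se(t)
    except UndefinedStatisticError:
        z, se = float("nan"), float("nan")
    try:
        alpha = compute_alpha_b(t)
    except UndefinedStatisticError:
        alpha = float("nan")
    return {
        "time_n": time_n,
        "bin": bin_label,
        "focal": focal,
        "s_n": t.s_n,
        "s_s": t.s_s,
        "r_n": t.r_n,
        "r_s": t.r_s,
        "z": z,
        "alpha_b": alpha,
        "mc_se": se,
        "n_replicates": n_rep,
    }


def z_curve_from_batch(
    batch: BatchResult,
    bin_width: float = 0.1,
    focal_pops: Sequence[str] = ("pop1", "pop2"),
) -> ZCurve:
    """Pool counts per time point and bin and compute Z for each focal population."""
    labels = _bin_labels(bin_width)
    rows = []
    for i, t_n in enumerate(batch.sample_times):
        n_rep = batch.n_retained(i)
        for focal in focal_pops:
            binned, _ = batch.pooled_counts(i, focal=focal, bin_width=bin_width)
            for label, table in zip(labels, binned.per_bin):
                rows.append(_rows_for_table(table, t_n, label, focal, n_rep))
            rows.append(_rows_for_table(binned.combined_above, t_n, ">0.1", focal, n_rep))
            rows.append(_rows_for_table(binned.total, t_n, "all", focal, n_rep))
    return ZCurve(
        frame=pd.DataFrame(rows),
        n_replicates=batch.n_replicates,
        manifest=dict(batch.manifest),
    )


def z_curve_experiment(
    config: ScenarioConfig,
    locus: LocusStructure,
    dfe: DFEParams | None = None,
    balanced: BalancedPolyConfig | None = None,
    replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    sample_times: Sequence[float] | None = None,
    dominance: DominanceModel = DominanceModel(),
    bin_width: float = 0.1,
) -> ZCurve:
    """Simulate a scenario and summarise pooled Z against time per frequency bin."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    batch = run_batch(
        config,
        locus,
        dfe=dfe,
        dominance=dominance,
        balanced=balanced,
        n_replicates=replicates,
        seed=seed,
        sample_times=sample_times,
    )
    return z_curve_from_batch(batch, bin_width=bin_width)


@dataclass(frozen=True)
class RecoveryResult:
    """Inferred vs true balanced fraction for one mix, time, bin and focal population."""

    mix_fraction: float
    sample_time: float
    bin: str
    focal: str
    true_alpha_b: float
    inferred_alpha_b: float
    ratio: float  # inferred/true; NaN where true == 0
    ratio_display: float  # negative inferred truncated to 0 for display
    s_n: float
    n_balanced_shared: float


def alpha_recovery_experiment(
    config: ScenarioConfig,
    locus: LocusStructure,
    dfe: DFEParams | None,
    balanced: BalancedPolyConfig,
    mix_fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    sample_times: Sequence[float] = (0.2, 1.0),
    replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    dominance: DominanceModel = DominanceModel(),
    bin_width: float = 0.1,
    focal_pops: Sequence[str] = ("pop1", "pop2"),
) -> list[RecoveryResult]:
    """Mix replicates with and without a balanced polymorphism and recover alpha_b.

    At each mix fraction lambda, counts from round(lambda*n) balancing
    replicates and (n - that) plain replicates are pooled; the true alpha_b is
    the fraction of shared nonsynonymous polymorphisms in the pool that are
    the flagged balanced mutations themselves (hitchhikers excluded by
    definition), and the inferred value is 1 - (S_S*R_N)/(S_N*R_S) on the
    pooled table.  Negative inferred values are truncated to zero only in
    ``ratio_display``; raw values are retained.
    """
    if any(not 0.0 <= f <= 1.0 for f in mix_fractions):
        raise ValueError("mix fractions must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batch_bal = run_batch(
        config, locus, dfe=dfe, dominance=dominance, balanced=balanced,
        n_replicates=replicates, seed=rng, sample_times=sample_times,
    )
    batch_plain = run_batch(
        config, locus, dfe=dfe, dominance=dominance, balanced=None,
        n_replicates=replicates, seed=rng, sample_times=sample_times,
    )
    return recovery_from_batches(
        batch_bal, batch_plain, mix_fractions=mix_fractions,
        bin_width=bin_width, focal_pops=focal_pops,
    )


def recovery_from_batches(
    batch_bal: BatchResult,
    batch_plain: BatchResult,
    mix_fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    bin_width: float = 0.1,
    focal_pops: Sequence[str] = ("pop1", "pop2"),
    time_indices: Sequence[int] | None = None,
) -> list[RecoveryResult]:
    """Recovery analysis over already-simulated balancing / plain batches."""
    if batch_bal.sample_times != batch_plain.sample_times:
        raise ValueError("batches must share their sample-time schedule")
    labels = _bin_labels(bin_width)
    n_bins = len(labels)
    out: list[RecoveryResult] = []
    indices = (
        list(time_indices)
        if time_indices is not None
        else list(range(len(batch_bal.sample_times)))
    )
    for ti in indices:
        t_n = batch_bal.sample_times[ti]
        for focal in focal_pops:
            cells_b, bal_b = batch_bal.replicate_cells(ti, focal, bin_width)
            keep = batch_bal.retained[ti]
            cells_b, bal_b = cells_b[keep], bal_b[keep]
            cells_p, _ = batch_plain.replicate_cells(ti, focal, bin_width)
            # prefix sums let any first-k replicate subset be pooled instantly
            cum_b = np.concatenate(
                [np.zeros((1, n_bins, 4)), cells_b.cumsum(axis=0)]
            )
            cum_bal = np.concatenate([np.zeros((1, n_bins)), bal_b.cumsum(axis=0)])
            cum_p = np.concatenate(
                [np.zeros((1, n_bins, 4)), cells_p.cumsum(axis=0)]
            )
            n_b, n_p = cells_b.shape[0], cells_p.shape[0]
            n_pool = min(n_b, n_p)
            for lam in mix_fractions:
                k_b = int(round(lam * n_pool))
                k_p = n_pool - k_b
                pooled = cum_b[k_b] + cum_p[k_p]
                balanced_counts = cum_bal[k_b]
                for bi, label in enumerate(labels):
                    t = PolymorphismCounts(*pooled[bi])
                    true_ab = (
                        balanced_counts[bi] / t.s_n if t.s_n > 0 else float("nan")
                    )
                    try:
                        inferred = compute_alpha_b(t)
                    except UndefinedStatisticError:
                        inferred = float("nan")
                    if true_ab and np.isfinite(true_ab) and true_ab > 0:
                        ratio = inferred / true_ab
                        ratio_disp = max(inferred, 0.0) / true_ab
                    else:
                        ratio = ratio_disp = float("nan")
                    out.append(
                        RecoveryResult(
                            mix_fraction=lam,
                            sample_time=t_n,
                            bin=label,
                            focal=focal,
                            true_alpha_b=float(true_ab),
                            inferred_alpha_b=float(inferred),
                            ratio=float(ratio),
                            ratio_display=float(ratio_disp),
                            s_n=float(t.s_n),
                            n_balanced_shared=float(balanced_counts[bi]),
                        )
                    )
    return out


def recovery_frame(results: Sequence[RecoveryResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class PowerResult:
    """Per-replicate Z distributions for a gene-shaped locus with/without balancing.

    ``overlap`` is the fraction of no-balancing replicates whose Z exceeds the
    median Z of the balancing replicates — near 0.5 means the distributions
    coincide, near 0 means clean separation.
    """

    z_with: np.ndarray
    z_without: np.ndarray
    n_dropped_with: int
    n_dropped_without: int
    overlap: float
    sample_time: float


def _per_replicate_z(batch: BatchResult, time_index: int, focal: str) -> tuple[np.ndarray, int]:
    cells, _ = batch.replicate_cells(time_index, focal=focal, bin_width=0.5)
    tot = cells[:, 0, :]  # single bin: all frequencies
    retained = batch.retained[time_index]
    tot = tot[retained]
    s_n, s_s, r_n, r_s = tot.T
    ok = (s_s > 0) & (r_n > 0) & (r_s > 0)
    z = (s_n[ok] / s_s[ok]) / (r_n[ok] / r_s[ok])
    return z, int((~ok).sum())


def single_gene_power_experiment(
    locus: LocusStructure | None = None,
    scale: int = 1,
    replicates: int = 200,
    seed: int | np.random.Generator | None = None,
    config: ScenarioConfig | None = None,
    dfe: DFEParams | None = None,
    balanced: BalancedPolyConfig | None = None,
    dominance: DominanceModel = DominanceModel(),
    sample_time: float = 1.0,
    focal: str = "pop1",
) -> PowerResult:
    """Distribution of per-replicate Z for a gene-shaped locus, with and without balancing.

    The locus defaults to the average human gene (9 exons of 288 bp) scaled by
    ``scale``; a balanced polymorphism sits at the centre of every exon in the
    with-balancing arm, and Z uses polymorphisms at all frequencies.  The
    default demography is a vicariance split into two equal halves.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100 for a usable distribution")
    locus = locus if locus is not None else LocusStructure.human_gene(scale=scale)
    if config is None:
        config = ScenarioConfig(
            mode="vicariance", split_fractions=(0.5, 0.5), sample_times=(sample_time,)
        )
    balanced = balanced if balanced is not None else BalancedPolyConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    batch_with = run_batch(
        config, locus, dfe=dfe, dominance=dominance, balanced=balanced,
        n_replicates=replicates, seed=rng, sample_times=(sample_time,),
    )
    batch_without = run_batch(
        config, locus, dfe=dfe, dominance=dominance, balanced=None,
        n_replicates=replicates, seed=rng, sample_times=(sample_time,),
    )
    z_with, drop_w = _per_replicate_z(batch_with, 0, focal)
    z_without, drop_wo = _per_replicate_z(batch_without, 0, focal)
    if len(z_with) == 0 or len(z_without) == 0:
        raise RuntimeError("all replicates had undefined Z; increase theta or replicates")
    overlap = float(np.mean(z_without > np.median(z_with)))
    return PowerResult(
        z_with=z_with,
        z_without=z_without,
        n_dropped_with=drop_w,
        n_dropped_without=drop_wo,
        overlap=overlap,
        sample_time=sample_time,
    )
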