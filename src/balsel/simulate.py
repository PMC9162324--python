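"""Forward Wright-Fisher simulation of a coding locus in a splitting population.

The model: an ancestral diploid population of size N evolves to mutation-
selection-drift equilibrium, optionally acquires a balanced polymorphism
maintained by negative frequency-dependent selection (NFDS), and then splits
into two descendant populations (duplication, vicariance, or dispersal, with
optional exponential expansion and symmetric migration).  Both descendants
are sampled at a schedule of times after the split, yielding per-site
frequency tables from which shared/private polymorphism counts are formed.

Sites are tracked as independent allele-frequency trajectories (per-site
biallelic mutation, deterministic selection with dominance, binomial drift);
sites are unlinked, so intronic and intergenic positions — neutral and
excluded from the count tables — need not be simulated.  Nonsynonymous
mutations draw selection coefficients from a gamma distribution of fitness
effects (DFE); dominance follows an inverse relationship with the selection
coefficient anchored at h = 0.5 for neutral mutations.

Two engines share this model: :func:`run_scenario` simulates one replicate at
a time (with the discard-and-redraw rule for lost balanced polymorphisms),
and :func:`run_batch` vectorises many replicates for Monte-Carlo experiments,
exploiting the independence of unlinked sites to simulate balanced-allele
trajectories separately from the neutral/deleterious background.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .counts import PolymorphismCounts
from .sites import BinnedCounts, SiteRecord, bin_by_frequency, classify_shared_private

__all__ = [
    "DFEParams",
    "DominanceModel",
    "BalancedPolyConfig",
    "LocusStructure",
    "ScenarioConfig",
    "SimSample",
    "ScenarioRun",
    "BatchResult",
    "HUMAN_DFE",
    "DROSOPHILA_DFE",
    "sample_dfe",
    "huber_dominance",
    "nfds_selection",
    "run_scenario",
    "run_batch",
    "classify_sim_sites",
    "allele_trajectories",
    "ScenarioFailureError",
]

# Most-negative selection coefficient tracked; more deleterious draws are
# effectively lethal and are capped here to keep genotype fitness positive.
_S_FLOOR = -0.99


class ScenarioFailureError(RuntimeError):
    """Raised when a required balanced polymorphism cannot be retained."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DFEParams:
    """Gamma distribution of deleterious fitness effects, on the N_e*s scale."""

    shape: float
    mean_scaled_s: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.mean_scaled_s < 0:
            raise ValueError("mean scaled selection strength must be non-negative")


HUMAN_DFE = DFEParams(shape=0.23, mean_scaled_s=425.0, label="human")
DROSOPHILA_DFE = DFEParams(shape=0.35, mean_scaled_s=1800.0, label="drosophila")


@dataclass(frozen=True)
class DominanceModel:
    """Dominance as a decreasing function of |s|: h = 1/(1/theta_intercept - theta_rate*s).

    With theta_intercept = 0.5 a neutral mutation is exactly codominant and h
    falls toward 0 as mutations become more deleterious.  ``fixed_h``
    short-circuits the relationship.
    """

    theta_intercept: float = 0.5
    theta_rate: float = 41225.56
    fixed_h: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_intercept <= 1.0:
            raise ValueError("theta_intercept must lie in (0, 1]")
        if self.theta_rate < 0:
            raise ValueError("theta_rate must be non-negative")


@dataclass(frozen=True)
class BalancedPolyConfig:
    """A balanced polymorphism under negative frequency-dependent selection.

    The equilibrium frequency is drawn uniformly on (0, 1) per replicate
    unless ``eq_freq`` fixes it; the restoring force is scaled so that
    N*s = ``scaled_ns_at_eq`` (N the ancestral size) for a rare allele.  The
    mutation is introduced ``intro_time_n`` (in N generations) before the
    split, at the centre of each exon.
    """

    scaled_ns_at_eq: float = 20.0
    eq_freq: float | None = None
    intro_time_n: float = 5.0
    init_freq: float | None = None  # default: one copy, 1/(2N)

    def __post_init__(self) -> None:
        if self.scaled_ns_at_eq <= 0:
            raise ValueError("scaled_ns_at_eq must be positive")
        if self.eq_freq is not None and not 0.0 < self.eq_freq < 1.0:
            raise ValueError("eq_freq must lie in (0, 1)")
        if self.intro_time_n < 0:
            raise ValueError("intro_time_n must be non-negative")


@dataclass(frozen=True)
class LocusStructure:
    """Exon/intron layout of the simulated locus.

    Introns are neutral and excluded from the count tables; under the
    unlinked-sites model they have no effect on coding-site dynamics, so only
    the concatenated exonic positions are simulated.  Within exons, positions
    at codon offset 3 are synonymous and offsets 1-2 nonsynonymous (a
    deterministic 2:1 nonsynonymous:synonymous rule).
    """

    exon_length: int = 288
    n_exons: int = 1
    intron_length: int = 5419
    n_introns: int = 0

    def __post_init__(self) -> None:
        if self.exon_length <= 0 or self.n_exons <= 0:
            raise ValueError("exon dimensions must be positive")
        if self.n_introns and self.n_introns != self.n_exons - 1:
            raise ValueError("gene-shaped loci require n_introns = n_exons - 1")

    @classmethod
    def single_exon(cls) -> "LocusStructure":
        return cls()

    @classmethod
    def human_gene(cls, scale: int = 1) -> "LocusStructure":
        """Average human gene: 9 exons of 288 bp separated by 8 introns of 5,419 bp."""
        return cls(exon_length=288, n_exons=9 * scale, intron_length=5419,
                   n_introns=9 * scale - 1)

    @property
    def coding_length(self) -> int:
        return self.exon_length * self.n_exons

    def is_nonsynonymous(self) -> np.ndarray:
        """Boolean mask over coding positions: True at codon offsets 1-2."""
        pos = np.arange(self.coding_length)
        return pos % 3 != 2

    def balanced_positions(self) -> np.ndarray:
        """Centre of each exon (coding coordinates)."""
        starts = np.arange(self.n_exons) * self.exon_length
        return starts + self.exon_length // 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Demography and rates for one split scenario.

    Sizes are diploid; times are expressed in units of the ancestral size N.
    ``split_fractions`` give daughter sizes as fractions of N (duplication
    requires both equal to 1).  ``expansion`` gives per-daughter final-size
    multipliers, reached exponentially ``expansion_end_n``*N generations after
    the split.  Migration is symmetric and conservative: each generation a
    fraction ``migration_rate`` of each population is replaced by migrants.
    """

    n_ancestral: int = 200
    mode: str = "duplication"
    split_fractions: tuple[float, float] = (1.0, 1.0)
    expansion: tuple[float, float] = (1.0, 1.0)
    expansion_end_n: float = 21.0
    migration_rate: float = 0.0
    mu: float = 2.5e-8
    r: float = 1.1e-8
    burn_in_n: float = 15.0
    sample_times: tuple[float, ...] = tuple(np.round(np.arange(1, 401) * 0.05, 2))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("duplication", "vicariance", "dispersal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(f <= 0 for f in self.split_fractions):
            raise ValueError("split fractions must be positive")
        if self.mode == "duplication" and self.split_fractions != (1.0, 1.0):
            raise ValueError("duplication requires both daughters at the ancestral size")
        if any(m < 1.0 for m in self.expansion):
            raise ValueError("expansion multipliers must be >= 1")
        if not 0.0 <= self.migration_rate < 1.0:
            raise ValueError("migration_rate must lie in [0, 1)")
        if list(self.sample_times) != sorted(self.sample_times):
            raise ValueError("sample_times must be sorted")
        if self.n_ancestral < 2:
            raise ValueError("n_ancestral must be at least 2")

    def rescaled(self, factor: float) -> "ScenarioConfig":
        """Jointly rescale N down and mu/r up by ``factor`` (times stay in N units).

        Selection coefficients scale automatically because the DFE is
        parameterised on the N_e*s scale against ``n_ancestral``.
        """
        return replace(
            self,
            n_ancestral=max(2, int(round(self.n_ancestral / factor))),
            mu=self.mu * factor,
            r=self.r * factor,
        )

    def daughter_sizes(self) -> tuple[int, int]:
        n = self.n_ancestral
        if self.mode == "duplication":
            return n, n
        if self.mode == "dispersal":
            # population 1 is the persisting ancestor
            return n, max(1, int(round(self.split_fractions[1] * n)))
        return (
            max(1, int(round(self.split_fractions[0] * n))),
            max(1, int(round(self.split_fractions[1] * n))),
        )


@dataclass
class SimSample:
    """Frequencies of segregating sites in both populations at one sample time."""

    time_n: float
    positions: np.ndarray
    freq_pop1: np.ndarray
    freq_pop2: np.ndarray
    is_nonsyn: np.ndarray
    is_balanced: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class ScenarioRun:
    """One retained replicate plus its manifest."""

    samples: list[SimSample]
    n_discarded: int
    seed: int | None
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# elementary model pieces


def sample_dfe(
    params: DFEParams, n: int, rng: np.random.Generator, n_e: float
) -> np.ndarray:
    """Draw ``n`` negative selection coefficients from the gamma DFE.

    |N_e*s| is gamma-distributed with the given shape and mean (N_e the
    ancestral size); returned s values are negative, floored at an effectively
    lethal value.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    if params.mean_scaled_s == 0:
        return np.zeros(n)
    scale = params.mean_scaled_s / params.shape
    scaled = rng.gamma(params.shape, scale, size=n)
    return np.maximum(-scaled / n_e, _S_FLOOR)


def huber_dominance(s, model: DominanceModel = DominanceModel()):
    """Dominance coefficient for selection coefficient ``s`` (s <= 0).

    h = 1/(1/theta_intercept - theta_rate*s): h = theta_intercept at s = 0,
    decreasing monotonically toward 0 as s becomes more negative.
    """
    if model.fixed_h is not None:
        return (
            np.full_like(np.asarray(s, dtype=float), model.fixed_h)
            if np.ndim(s)
            else model.fixed_h
        )
    s_arr = np.asarray(s, dtype=float)
    h = 1.0 / (1.0 / model.theta_intercept - model.theta_rate * s_arr)
    return h if np.ndim(s) else float(h)


def nfds_selection(
    current_freq,
    config: BalancedPolyConfig,
    n_ancestral: float,
    eq_freq: float | np.ndarray | None = None,
):
    """Frequency-dependent selection coefficient s(p) = s0*(1 - p/p_eq).

    Zero at the equilibrium frequency, positive below it and negative above
    (a restoring force), with strength anchored so that N*s0 equals
    ``scaled_ns_at_eq`` in the ancestral population.
    """
    p_eq = eq_freq if eq_freq is not None else config.eq_freq
    if p_eq is None:
        raise ValueError("an equilibrium frequency is required")
    s0 = config.scaled_ns_at_eq / n_ancestral
    p = np.asarray(current_freq, dtype=float)
    s = s0 * (1.0 - p / np.asarray(p_eq, dtype=float))
    return s if np.ndim(current_freq) or np.ndim(p_eq) else float(s)


def _selection_update(p: np.ndarray, s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Deterministic one-generation change under genotype fitnesses 1, 1+hs, 1+s."""
    w12 = np.maximum(1.0 + h * s, 0.0)
    w22 = np.maximum(1.0 + s, 0.0)
    q = 1.0 - p
    num = p * p * w22 + p * q * w12
    den = p * p * w22 + 2.0 * p * q * w12 + q * q
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / den, 0.0)
    return out


def allele_trajectories(
    p0,
    pop_size: int,
    n_gens: int,
    n_reps: int,
    rng: np.random.Generator,
    s: float = 0.0,
    h: float = 0.5,
    eq_freq=None,
    s0: float | None = None,
    record: bool = False,
):
    """Simulate independent single-site Wright-Fisher trajectories.

    With ``eq_freq`` (and ``s0``) set, selection is frequency dependent,
    s(p) = s0*(1 - p/p_eq); otherwise the constant ``s``/``h`` apply.  Returns
    the final frequencies, or the full (n_gens+1, n_reps) array if ``record``.
    """
    two_n = 2 * pop_size
    p = np.broadcast_to(np.asarray(p0, dtype=float), (n_reps,)).copy()
    traj = np.empty((n_gens + 1, n_reps)) if record else None
    if record:
        traj[0] = p
    h_arr = np.full(n_reps, h)
    for t in range(n_gens):
        if eq_freq is not None:
            s_t = s0 * (1.0 - p / np.asarray(eq_freq, dtype=float))
        else:
            s_t = np.full(n_reps, s)
        if np.any(s_t != 0.0):
            p = _selection_update(p, s_t, h_arr)
        p = rng.binomial(two_n, np.clip(p, 0.0, 1.0)) / two_n
        if record:
            traj[t + 1] = p
    return traj if record else p


# ---------------------------------------------------------------------------
# scalar engine (one replicate)


class _PopState:
    """Segregating sites of one replicate: parallel arrays keyed by coding position."""

    def __init__(self, locus: LocusStructure) -> None:
        self.locus = locus
        self.nonsyn_mask = locus.is_nonsynonymous()
        self.pos = np.empty(0, dtype=np.int64)
        self.s = np.empty(0)
        self.h = np.empty(0)
        self.is_balanced = np.empty(0, dtype=bool)
        self.p_eq = np.empty(0)
        self.p = np.empty(0)

    def occupied(self) -> np.ndarray:
        occ = np.zeros(self.locus.coding_length, dtype=bool)
        occ[self.pos] = True
        return occ


def _mutate_scalar(
    state: _PopState,
    rng: np.random.Generator,
    n_new: int,
    init_freq: float,
    dfe: DFEParams | None,
    dominance: DominanceModel,
    n_e: float,
) -> None:
    if n_new <= 0:
        return
    occ = state.occupied()
    free = np.flatnonzero(~occ)
    if len(free) == 0:
        return
    n_new = min(n_new, len(free))
    pos = rng.choice(free, size=n_new, replace=False)
    nonsyn = state.nonsyn_mask[pos]
    s = np.zeros(n_new)
    if dfe is not None and nonsyn.any():
        s[nonsyn] = sample_dfe(dfe, int(nonsyn.sum()), rng, n_e)
    h = np.asarray(huber_dominance(s, dominance), dtype=float)
    state.pos = np.concatenate([state.pos, pos])
    state.s = np.concatenate([state.s, s])
    state.h = np.concatenate([state.h, h])
    state.is_balanced = np.concatenate([state.is_balanced, np.zeros(n_new, dtype=bool)])
    state.p_eq = np.concatenate([state.p_eq, np.full(n_new, np.nan)])
    state.p = np.concatenate([state.p, np.full(n_new, init_freq)])


def _step_freqs(
    p: np.ndarray,
    s: np.ndarray,
    h: np.ndarray,
    is_balanced: np.ndarray,
    p_eq: np.ndarray,
    two_n: int,
    rng: np.random.Generator,
    ns_at_eq: float,
    n_ancestral: int,
) -> np.ndarray:
    s_eff = s.copy()
    if is_balanced.any():
        s0 = ns_at_eq / n_ancestral
        pb = p[is_balanced]
        s_eff[is_balanced] = s0 * (1.0 - pb / p_eq[is_balanced])
    h_eff = np.where(is_balanced, 0.5, h)
    p2 = _selection_update(p, s_eff, h_eff)
    return rng.binomial(two_n, np.clip(p2, 0.0, 1.0)) / two_n


def _attempt_scenario(
    config: ScenarioConfig,
    locus: LocusStructure,
    dfe: DFEParams | None,
    dominance: DominanceModel,
    balanced: BalancedPolyConfig | None,
    rng: np.random.Generator,
) -> list[SimSample] | None:
    """One full replicate; None signals a discarded run (balanced allele lost)."""
    n = config.n_ancestral
    two_n = 2 * n
    state = _PopState(locus)
    lam = two_n * locus.coding_length * config.mu
    burn = int(round(config.burn_in_n * n))
    ns_at_eq = balanced.scaled_ns_at_eq if balanced is not None else 0.0

    def one_pop_gen() -> None:
        state.p = _step_freqs(
            state.p, state.s, state.h, state.is_balanced, state.p_eq,
            two_n, rng, ns_at_eq, n,
        )
        # losses prune; substitutions free their site
        keep = (state.p > 0.0) & (state.p < 1.0)
        for name in ("pos", "s", "h", "is_balanced", "p_eq", "p"):
            setattr(state, name, getattr(state, name)[keep])
        _mutate_scalar(state, rng, rng.poisson(lam), 1.0 / two_n, dfe, dominance, n)

    for _ in range(burn):
        one_pop_gen()

    if balanced is not None:
        positions = locus.balanced_positions()
        occ = state.occupied()
        for bp in positions:
            if occ[bp]:
                keep = state.pos != bp
                for name in ("pos", "s", "h", "is_balanced", "p_eq", "p"):
                    setattr(state, name, getattr(state, name)[keep])
            p_eq = balanced.eq_freq if balanced.eq_freq is not None else rng.uniform()
            init = balanced.init_freq if balanced.init_freq is not None else 1.0 / two_n
            state.pos = np.concatenate([state.pos, [bp]])
            state.s = np.concatenate([state.s, [0.0]])
            state.h = np.concatenate([state.h, [0.5]])
            state.is_balanced = np.concatenate([state.is_balanced, [True]])
            state.p_eq = np.concatenate([state.p_eq, [p_eq]])
            state.p = np.concatenate([state.p, [init]])
        intro = int(round(balanced.intro_time_n * n))
        for _ in range(intro):
            one_pop_gen()
        if not state.is_balanced.any():
            return None

    # split
    n1, n2 = config.daughter_sizes()
    if config.mode == "duplication":
        p1, p2 = state.p.copy(), state.p.copy()
    elif config.mode == "dispersal":
        p1 = state.p.copy()
        p2 = rng.binomial(2 * n2, state.p) / (2 * n2)
    else:
        p1 = rng.binomial(2 * n1, state.p) / (2 * n1)
        p2 = rng.binomial(2 * n2, state.p) / (2 * n2)

    max_gen = int(round(config.sample_times[-1] * n))
    sched1, sched2 = _size_schedules(config, max_gen, n1, n2)
    sample_gens = {int(round(t * n)): t for t in config.sample_times}
    samples: list[SimSample] = []
    m = config.migration_rate

    pos, s, h, is_bal, p_eq = state.pos, state.s, state.h, state.is_balanced, state.p_eq
    nonsyn_mask = state.nonsyn_mask

    def record(t_n: float) -> None:
        seg = ((p1 > 0) & (p1 < 1)) | ((p2 > 0) & (p2 < 1))
        samples.append(
            SimSample(
                time_n=t_n,
                positions=pos[seg].copy(),
                freq_pop1=p1[seg].copy(),
                freq_pop2=p2[seg].copy(),
                is_nonsyn=nonsyn_mask[pos[seg]],
                is_balanced=is_bal[seg].copy(),
            )
        )

    if 0 in sample_gens:  # pragma: no cover - time zero rarely sampled
        record(sample_gens[0])
    for g in range(1, max_gen + 1):
        n1_t, n2_t = sched1[g - 1], sched2[g - 1]
        if m > 0.0:
            p1, p2 = (1 - m) * p1 + m * p2, (1 - m) * p2 + m * p1
        p1 = _step_freqs(p1, s, h, is_bal, p_eq, 2 * n1_t, rng, ns_at_eq, n)
        p2 = _step_freqs(p2, s, h, is_bal, p_eq, 2 * n2_t, rng, ns_at_eq, n)
        if balanced is not None and g in sample_gens:
            bal_alive = (
                (p1[is_bal] > 0) & (p1[is_bal] < 1) & (p2[is_bal] > 0) & (p2[is_bal] < 1)
            )
            if not bal_alive.any():
                return None
        # prune sites monomorphic in both populations
        keep = ~(((p1 == 0) | (p1 == 1)) & ((p2 == 0) | (p2 == 1)))
        pos, s, h, is_bal, p_eq = pos[keep], s[keep], h[keep], is_bal[keep], p_eq[keep]
        p1, p2 = p1[keep], p2[keep]
        # mutation in each daughter
        for which, n_t in ((1, n1_t), (2, n2_t)):
            occ = np.zeros(locus.coding_length, dtype=bool)
            occ[pos] = True
            free = np.flatnonzero(~occ)
            k = min(rng.poisson(2 * n_t * locus.coding_length * config.mu), len(free))
            if k <= 0:
                continue
            new_pos = rng.choice(free, size=k, replace=False)
            new_nonsyn = nonsyn_mask[new_pos]
            new_s = np.zeros(k)
            if dfe is not None and new_nonsyn.any():
                new_s[new_nonsyn] = sample_dfe(dfe, int(new_nonsyn.sum()), rng, n)
            new_h = np.asarray(huber_dominance(new_s, dominance), dtype=float)
            pos = np.concatenate([pos, new_pos])
            s = np.concatenate([s, new_s])
            h = np.concatenate([h, new_h])
            is_bal = np.concatenate([is_bal, np.zeros(k, dtype=bool)])
            p_eq = np.concatenate([p_eq, np.full(k, np.nan)])
            init = 1.0 / (2 * n_t)
            if which == 1:
                p1 = np.concatenate([p1, np.full(k, init)])
                p2 = np.concatenate([p2, np.zeros(k)])
            else:
                p1 = np.concatenate([p1, np.zeros(k)])
                p2 = np.concatenate([p2, np.full(k, init)])
        if g in sample_gens:
            record(sample_gens[g])
    return samples


def _size_schedules(
    config: ScenarioConfig, max_gen: int, n1: int, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation daughter sizes, with exponential expansion if configured."""
    t_end = max(1, int(round(config.expansion_end_n * config.n_ancestral)))
    gens = np.arange(1, max_gen + 1)
    out = []
    for n0, mult in zip((n1, n2), config.expansion):
        if mult == 1.0:
            out.append(np.full(max_gen, n0, dtype=np.int64))
        else:
            frac = np.minimum(gens / t_end, 1.0)
            out.append(np.maximum(1, np.round(n0 * mult**frac)).astype(np.int64))
    return out[0], out[1]


def run_scenario(
    config: ScenarioConfig,
    locus: LocusStructure,
    dfe: DFEParams | None = None,
    dominance: DominanceModel = DominanceModel(),
    balanced: BalancedPolyConfig | None = None,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 200,
) -> ScenarioRun:
    """Simulate one replicate of the scenario, redrawing if the balanced allele is lost.

    Replicates in which a required balanced polymorphism is absent from either
    population at any post-split generation up to the last sample time are
    discarded and re-drawn with a fresh seed stream; the discard count is
    reported.  ``ScenarioFailureError`` is raised after ``max_retries``
    consecutive discards.
    """
    base_seed = seed if not isinstance(seed, np.random.Generator) else None
    if base_seed is None and config.seed is not None:
        base_seed = config.seed
    discards = 0
    for attempt in range(max_retries + 1):
        if isinstance(seed, np.random.Generator) and attempt == 0:
            rng = seed
        else:
            rng = np.random.default_rng(
                None if base_seed is None else base_seed + attempt
            )
        samples = _attempt_scenario(config, locus, dfe, dominance, balanced, rng)
        if samples is not None:
            return ScenarioRun(
                samples=samples, n_discarded=discards, seed=base_seed, config=config
            )
        discards += 1
    raise ScenarioFailureError(
        f"balanced polymorphism lost in all {max_retries + 1} attempts"
    )


def classify_sim_sites(
    sample: SimSample,
    focal: str = "pop1",
    bin_width: float = 0.1,
) -> BinnedCounts:
    """Bridge a simulation sample into the shared/private binning pipeline.

    Exonic sites carry their codon-rule functional class; the balanced flag is
    not used here (the classifier sees only frequencies and classes).
    """
    records = [
        SiteRecord(
            chrom="sim",
            pos=int(p) + 1,
            ref_allele="A",
            alt_allele="T",
            freq_by_pop={"pop1": f1, "pop2": f2},
            func_class="nonsynonymous" if ns else "synonymous",
            gene_id="locus",
        )
        for p, f1, f2, ns in zip(
            sample.positions, sample.freq_pop1, sample.freq_pop2, sample.is_nonsyn
        )
    ]
    classified = classify_shared_private(records, "pop1", "pop2", focal)
    focal_private = "private_pop1" if focal == "pop1" else "private_pop2"
    return bin_by_frequency(classified, bin_width=bin_width, focal_private=focal_private)


# ---------------------------------------------------------------------------
# batch engine (vectorised across replicates)


@dataclass
class BatchResult:
    """Vectorised simulation output: per-time flattened site tables across replicates.

    ``site_tables[i]`` holds arrays (rep, p1, p2, is_nonsyn) for sample time
    ``sample_times[i]``; ``balanced`` holds per-replicate balanced-allele
    frequencies and retention masks when a balanced polymorphism was
    simulated.  ``retained[i]`` marks replicates in which every required
    balanced polymorphism criterion holds at that time (all True without
    balancing selection).
    """

    config: ScenarioConfig
    sample_times: tuple[float, ...]
    n_replicates: int
    site_tables: list[dict[str, np.ndarray]]
    retained: list[np.ndarray]
    balanced_tables: list[dict[str, np.ndarray]] | None
    n_attempts: int
    manifest: dict = field(default_factory=dict)

    def replicate_cells(
        self, time_index: int, focal: str = "pop1", bin_width: float = 0.1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-replicate, per-bin cell counts at one sample time.

        Returns ``(cells, bal_counts)``: cells has shape (n_replicates,
        n_bins, 4) with columns s_n, s_s, r_n, r_s over folded-MAF bins of the
        focal population; bal_counts (n_replicates, n_bins) counts shared
        balanced nonsynonymous sites.  Non-retained replicates are zeroed.
        """
        tab = self.site_tables[time_index]
        n_bins = int(round(0.5 / bin_width))
        cells = np.zeros((self.n_replicates, n_bins, 4))
        self._accumulate(cells, tab, focal, bin_width, flag=None)
        bal = np.zeros((self.n_replicates, n_bins))
        if self.balanced_tables is not None:
            self._accumulate_balanced(bal, self.balanced_tables[time_index], focal, bin_width)
        mask = self.retained[time_index]
        cells[~mask] = 0.0
        bal[~mask] = 0.0
        return cells, bal

    @staticmethod
    def _accumulate(cells, tab, focal, bin_width, flag) -> None:
        pf = tab["p1"] if focal == "pop1" else tab["p2"]
        po = tab["p2"] if focal == "pop1" else tab["p1"]
        seg_f = (pf > 0) & (pf < 1)
        seg_o = (po > 0) & (po < 1)
        shared = seg_f & seg_o
        keep = seg_f  # shared or focal-private
        rep = tab["rep"][keep]
        maf = np.minimum(pf[keep], 1.0 - pf[keep])
        n_bins = cells.shape[1]
        idx = np.minimum(np.ceil(maf / bin_width).astype(np.int64) - 1, n_bins - 1)
        nonsyn = tab["is_nonsyn"][keep]
        col = np.where(shared[keep], np.where(nonsyn, 0, 1), np.where(nonsyn, 2, 3))
        np.add.at(cells, (rep, idx, col), 1.0)

    @staticmethod
    def _accumulate_balanced(bal, btab, focal, bin_width) -> None:
        pf = btab["p1"] if focal == "pop1" else btab["p2"]
        po = btab["p2"] if focal == "pop1" else btab["p1"]
        shared = (pf > 0) & (pf < 1) & (po > 0) & (po < 1)
        rep = btab["rep"][shared]
        maf = np.minimum(pf[shared], 1.0 - pf[shared])
        n_bins = bal.shape[1]
        idx = np.minimum(np.ceil(maf / bin_width).astype(np.int64) - 1, n_bins - 1)
        np.add.at(bal, (rep, idx), 1.0)

    def pooled_counts(
        self, time_index: int, focal: str = "pop1", bin_width: float = 0.1
    ) -> tuple[BinnedCounts, np.ndarray]:
        """Pooled per-bin count tables (ratio-of-sums input) and balanced-site counts."""
        cells, bal = self.replicate_cells(time_index, focal, bin_width)
        tot = cells.sum(axis=0)
        n_bins = tot.shape[0]
        per_bin = [PolymorphismCounts(*row) for row in tot]
        above = tot[1:].sum(axis=0)
        binned = BinnedCounts(
            bin_edges=np.linspace(0, 0.5, n_bins + 1),
            per_bin=per_bin,
            combined_above=PolymorphismCounts(*above),
            flagged=[False] * n_bins,
        )
        return binned, bal.sum(axis=0)

    def n_retained(self, time_index: int) -> int:
        return int(self.retained[time_index].sum())


class _BatchPop:
    """Flattened segregating-site arrays across replicates for one phase."""

    def __init__(self, n_reps: int, locus: LocusStructure) -> None:
        self.n_reps = n_reps
        self.locus = locus
        self.L = locus.coding_length
        self.nonsyn_mask = locus.is_nonsynonymous()
        self.rep = np.empty(0, dtype=np.int64)
        self.pos = np.empty(0, dtype=np.int64)
        self.s = np.empty(0)
        self.h = np.empty(0)
        self.occupied = np.zeros((n_reps, locus.coding_length), dtype=bool)


def _batch_mutate(
    bp: _BatchPop,
    rng: np.random.Generator,
    lam_per_rep: float,
    dfe: DFEParams | None,
    dominance: DominanceModel,
    n_e: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw new mutations across all replicates; collisions are redrawn up to 3 rounds."""
    k_total = rng.poisson(lam_per_rep * bp.n_reps)
    reps = np.empty(0, dtype=np.int64)
    poss = np.empty(0, dtype=np.int64)
    remaining = k_total
    for _ in range(3):
        if remaining <= 0:
            break
        cand_rep = rng.integers(0, bp.n_reps, size=remaining)
        cand_pos = rng.integers(0, bp.L, size=remaining)
        key = cand_rep * bp.L + cand_pos
        # drop within-batch duplicates and already-occupied sites
        _, first = np.unique(key, return_index=True)
        cand_rep, cand_pos = cand_rep[first], cand_pos[first]
        ok = ~bp.occupied[cand_rep, cand_pos]
        cand_rep, cand_pos = cand_rep[ok], cand_pos[ok]
        bp.occupied[cand_rep, cand_pos] = True
        reps = np.concatenate([reps, cand_rep])
        poss = np.concatenate([poss, cand_pos])
        remaining = k_total - len(reps)
    nonsyn = bp.nonsyn_mask[poss]
    s = np.zeros(len(poss))
    if dfe is not None and nonsyn.any():
        s[nonsyn] = sample_dfe(dfe, int(nonsyn.sum()), rng, n_e)
    h = np.asarray(huber_dominance(s, dominance), dtype=float)
    return reps, poss, s, h


def run_batch(
    config: ScenarioConfig,
    locus: LocusStructure,
    dfe: DFEParams | None = None,
    dominance: DominanceModel = DominanceModel(),
    balanced: BalancedPolyConfig | None = None,
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    sample_times: Sequence[float] | None = None,
    attempt_factor: int = 40,
) -> BatchResult:
    """Vectorised multi-replicate simulation of a split scenario.

    Because sites are unlinked, the balanced-allele trajectory is independent
    of the background: balanced trajectories are simulated for many attempts,
    attempts retained at the first sample time are paired one-to-one with
    independently simulated backgrounds, and the retention mask is refined at
    each later sample time.  Counts must therefore be pooled through
    :meth:`BatchResult.pooled_counts`, which applies the masks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = tuple(sample_times) if sample_times is not None else config.sample_times
    if list(times) != sorted(times) or not times:
        raise ValueError("sample_times must be non-empty and sorted")
    n = config.n_ancestral
    two_n = 2 * n
    n1, n2 = config.daughter_sizes()
    max_gen = int(round(times[-1] * n))
    sample_gens = [int(round(t * n)) for t in times]
    burn = int(round(config.burn_in_n * n))
    pre_split_extra = int(round(balanced.intro_time_n * n)) if balanced else 0
    sched1, sched2 = _size_schedules(config, max_gen, n1, n2)
    m = config.migration_rate

    # --- balanced-allele trajectories (factorised from the background) -----
    # one balanced allele per exon; a replicate is retained at a sample time
    # if at least one of its balanced alleles segregates in both populations
    bal_p1 = bal_p2 = None
    retained_masks: list[np.ndarray]
    if balanced is not None:
        n_att = attempt_factor * n_replicates
        n_bal = locus.n_exons
        shape = (n_att, n_bal)
        if balanced.eq_freq is not None:
            p_eq = np.full(shape, balanced.eq_freq)
        else:
            p_eq = rng.uniform(0.0, 1.0, size=shape)
        s0 = balanced.scaled_ns_at_eq / n
        half = np.full(shape, 0.5)
        init = balanced.init_freq if balanced.init_freq is not None else 1.0 / two_n
        p = np.full(shape, init)
        for _ in range(pre_split_extra):
            p = _selection_update(p, s0 * (1.0 - p / p_eq), half)
            p = rng.binomial(two_n, np.clip(p, 0.0, 1.0)) / two_n
        if config.mode == "duplication":
            bp1, bp2 = p.copy(), p.copy()
        elif config.mode == "dispersal":
            bp1 = p.copy()
            bp2 = rng.binomial(2 * n2, p) / (2 * n2)
        else:
            bp1 = rng.binomial(2 * n1, p) / (2 * n1)
            bp2 = rng.binomial(2 * n2, p) / (2 * n2)
        bal_at_times: list[tuple[np.ndarray, np.ndarray]] = []
        for g in range(1, max_gen + 1):
            if m > 0.0:
                bp1, bp2 = (1 - m) * bp1 + m * bp2, (1 - m) * bp2 + m * bp1
            bp1 = _selection_update(bp1, s0 * (1.0 - bp1 / p_eq), half)
            bp1 = rng.binomial(2 * sched1[g - 1], np.clip(bp1, 0, 1)) / (2 * sched1[g - 1])
            bp2 = _selection_update(bp2, s0 * (1.0 - bp2 / p_eq), half)
            bp2 = rng.binomial(2 * sched2[g - 1], np.clip(bp2, 0, 1)) / (2 * sched2[g - 1])
            if g in sample_gens:
                bal_at_times.append((bp1.copy(), bp2.copy()))
        alive = [
            ((q1 > 0) & (q1 < 1) & (q2 > 0) & (q2 < 1)).any(axis=1)
            for q1, q2 in bal_at_times
        ]
        chosen = np.flatnonzero(alive[0])[:n_replicates]
        if len(chosen) == 0:
            raise ScenarioFailureError(
                "no balanced polymorphism survived to the first sample time"
            )
        n_use = len(chosen)
        bal_p1 = [q1[chosen] for q1, _ in bal_at_times]
        bal_p2 = [q2[chosen] for _, q2 in bal_at_times]
        retained_masks = [a[chosen] for a in alive]
        n_attempts = n_att
    else:
        n_use = n_replicates
        retained_masks = [np.ones(n_use, dtype=bool) for _ in times]
        n_attempts = n_replicates

    # --- background (neutral + DFE sites), all replicates at once ----------
    bp = _BatchPop(n_use, locus)
    if balanced is not None:
        # reserve the balanced positions so background mutation never lands there
        bp.occupied[:, locus.balanced_positions()] = True
    lam = two_n * locus.coding_length * config.mu
    p = np.empty(0)

    def prune(keep: np.ndarray, freqs: list[np.ndarray]) -> list[np.ndarray]:
        lost = ~keep
        bp.occupied[bp.rep[lost], bp.pos[lost]] = False
        bp.rep, bp.pos, bp.s, bp.h = (
            bp.rep[keep], bp.pos[keep], bp.s[keep], bp.h[keep],
        )
        return [f[keep] for f in freqs]

    for _ in range(burn + pre_split_extra):
        if len(p):
            if dfe is not None:
                p = _selection_update(p, bp.s, bp.h)
            p = rng.binomial(two_n, np.clip(p, 0.0, 1.0)) / two_n
            (p,) = prune((p > 0.0) & (p < 1.0), [p])
        reps, poss, s, h = _batch_mutate(bp, rng, lam, dfe, dominance, n)
        bp.rep = np.concatenate([bp.rep, reps])
        bp.pos = np.concatenate([bp.pos, poss])
        bp.s = np.concatenate([bp.s, s])
        bp.h = np.concatenate([bp.h, h])
        p = np.concatenate([p, np.full(len(reps), 1.0 / two_n)])

    if config.mode == "duplication":
        p1, p2 = p.copy(), p.copy()
    elif config.mode == "dispersal":
        p1 = p.copy()
        p2 = rng.binomial(2 * n2, p) / (2 * n2)
    else:
        p1 = rng.binomial(2 * n1, p) / (2 * n1)
        p2 = rng.binomial(2 * n2, p) / (2 * n2)

    site_tables: list[dict[str, np.ndarray]] = []
    sample_set = {g: i for i, g in enumerate(sample_gens)}
    for g in range(1, max_gen + 1):
        n1_t, n2_t = int(sched1[g - 1]), int(sched2[g - 1])
        if m > 0.0:
            p1, p2 = (1 - m) * p1 + m * p2, (1 - m) * p2 + m * p1
        if dfe is not None:
            p1 = _selection_update(p1, bp.s, bp.h)
            p2 = _selection_update(p2, bp.s, bp.h)
        p1 = rng.binomial(2 * n1_t, np.clip(p1, 0.0, 1.0)) / (2 * n1_t)
        p2 = rng.binomial(2 * n2_t, np.clip(p2, 0.0, 1.0)) / (2 * n2_t)
        keep = ~(((p1 == 0.0) | (p1 == 1.0)) & ((p2 == 0.0) | (p2 == 1.0)))
        p1, p2 = prune(keep, [p1, p2])
        for which, n_t in ((1, n1_t), (2, n2_t)):
            lam_t = 2 * n_t * locus.coding_length * config.mu
            reps, poss, s, h = _batch_mutate(bp, rng, lam_t, dfe, dominance, n)
            bp.rep = np.concatenate([bp.rep, reps])
            bp.pos = np.concatenate([bp.pos, poss])
            bp.s = np.concatenate([bp.s, s])
            bp.h = np.concatenate([bp.h, h])
            init = 1.0 / (2 * n_t)
            zero = np.zeros(len(reps))
            if which == 1:
                p1 = np.concatenate([p1, np.full(len(reps), init)])
                p2 = np.concatenate([p2, zero])
            else:
                p1 = np.concatenate([p1, zero])
                p2 = np.concatenate([p2, np.full(len(reps), init)])
        if g in sample_set:
            site_tables.append(
                {
                    "rep": bp.rep.copy(),
                    "p1": p1.copy(),
                    "p2": p2.copy(),
                    "is_nonsyn": bp.nonsyn_mask[bp.pos],
                }
            )

    balanced_tables = None
    if balanced is not None:
        n_bal = locus.n_exons
        rep_flat = np.repeat(np.arange(n_use, dtype=np.int64), n_bal)
        balanced_tables = [
            {"rep": rep_flat, "p1": bal_p1[i].ravel(), "p2": bal_p2[i].ravel()}
            for i in range(len(times))
        ]
        # fold balanced sites into the site tables so pooled Z sees them;
        # rows monomorphic in both populations contribute nothing downstream
        for i, tab in enumerate(site_tables):
            reps_b = np.flatnonzero(retained_masks[i])
            rep_add = np.repeat(reps_b, n_bal)
            tab["rep"] = np.concatenate([tab["rep"], rep_add])
            tab["p1"] = np.concatenate([tab["p1"], bal_p1[i][reps_b].ravel()])
            tab["p2"] = np.concatenate([tab["p2"], bal_p2[i][reps_b].ravel()])
            tab["is_nonsyn"] = np.concatenate(
                [tab["is_nonsyn"], np.ones(len(rep_add), dtype=bool)]
            )

    manifest = {
        "mode": config.mode,
        "n_ancestral": n,
        "daughter_sizes": (n1, n2),
        "mu": config.mu,
        "migration_rate": m,
        "n_replicates_requested": n_replicates,
        "n_replicates_used": n_use,
        "n_attempts": n_attempts,
        "engine": "unlinked-site frequency tracking (batch)",
    }
    return BatchResult(
        config=config,
        sample_times=times,
        n_replicates=n_use,
        site_tables=site_tables,
        retained=retained_masks,
        balanced_tables=balanced_tables,
        n_attempts=n_attempts,
        manifest=manifest,
    )
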