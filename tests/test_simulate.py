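"""Tests for the Wright-Fisher engine: DFE, dominance, NFDS, scenarios, batching."""

import numpy as np
import pytest

from balsel.simulate import (
    DROSOPHILA_DFE,
    HUMAN_DFE,
    BalancedPolyConfig,
    DFEParams,
    DominanceModel,
    LocusStructure,
    ScenarioConfig,
    SimSample,
    allele_trajectories,
    classify_sim_sites,
    huber_dominance,
    nfds_selection,
    run_batch,
    run_scenario,
    sample_dfe,
)


class TestDFE:
    def test_empty_draw(self, rng):
        assert sample_dfe(HUMAN_DFE, 0, rng, n_e=200).size == 0

    def test_mean_scaled_strength(self, rng):
        # large N_e so the lethality floor never binds
        n_e = 1e6
        s = sample_dfe(HUMAN_DFE, 1_000_000, rng, n_e=n_e)
        assert (s <= 0).all()
        assert np.mean(np.abs(s) * n_e) == pytest.approx(425.0, rel=0.01)

    def test_gamma_coefficient_of_variation(self, rng):
        n_e = 1e6
        s = np.abs(sample_dfe(DROSOPHILA_DFE, 500_000, rng, n_e=n_e)) * n_e
        cv2 = s.var() / s.mean() ** 2
        assert cv2 == pytest.approx(1.0 / DROSOPHILA_DFE.shape, rel=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            DFEParams(shape=0.0, mean_scaled_s=1.0)
        with pytest.raises(ValueError):
            DFEParams(shape=0.5, mean_scaled_s=-1.0)


class TestDominance:
    def test_neutral_mutation_is_codominant(self):
        assert huber_dominance(0.0) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # h = 1/(1/0.5 - 41225.56*(-0.001)) = 1/(2 + 41.22556)
        assert huber_dominance(-0.001) == pytest.approx(1.0 / 43.22556, rel=1e-9)

    def test_monotone_decreasing_toward_zero(self):
        s = -np.logspace(-6, 0, 50)
        h = huber_dominance(s)
        assert (np.diff(h[np.argsort(s)]) >= 0).all()
        assert huber_dominance(-1e6) == pytest.approx(0.0, abs=1e-6)
        assert (h > 0).all() and (h <= 0.5).all()

    def test_fixed_h_overrides(self):
        model = DominanceModel(fixed_h=0.1)
        assert huber_dominance(-0.5, model) == 0.1


class TestNFDS:
    def test_restoring_force(self):
        cfg = BalancedPolyConfig(eq_freq=0.4)
        assert nfds_selection(0.4, cfg, 200) == pytest.approx(0.0)
        assert nfds_selection(0.1, cfg, 200) > 0
        assert nfds_selection(0.9, cfg, 200) < 0
        # strength anchored to the ancestral size: N*s(0) = 20
        assert nfds_selection(0.0, cfg, 200) == pytest.approx(20.0 / 200)

    @pytest.mark.parametrize("p_eq", [0.3, 0.5, 0.7])
    def test_stationary_around_equilibrium(self, p_eq, rng):
        cfg = BalancedPolyConfig(eq_freq=p_eq)
        traj = allele_trajectories(
            p_eq, pop_size=200, n_gens=2000, n_reps=40, rng=rng,
            eq_freq=p_eq, s0=cfg.scaled_ns_at_eq / 200, record=True,
        )
        tail = traj[500:]
        alive = (tail > 0) & (tail < 1)
        assert np.mean(tail[alive]) == pytest.approx(p_eq, abs=0.05)

    def test_persistence_exceeds_neutral_tenfold(self, rng):
        # median persistence of an NFDS allele vs a neutral allele from the same start
        n, p0 = 50, 0.3
        def loss_times(use_nfds, reps, cap):
            p = np.full(reps, p0)
            t_loss = np.full(reps, cap)
            active = np.ones(reps, dtype=bool)
            for t in range(1, cap + 1):
                if use_nfds:
                    s = (20.0 / n) * (1.0 - p / p0)
                    w12, w22 = 1 + 0.5 * s, 1 + s
                    q = 1 - p
                    p = (p * p * w22 + p * q * w12) / (
                        p * p * w22 + 2 * p * q * w12 + q * q
                    )
                p = rng.binomial(2 * n, np.clip(p, 0, 1)) / (2 * n)
                absorbed = active & ((p == 0) | (p == 1))
                t_loss[absorbed] = t
                active &= ~absorbed
                if not active.any():
                    break
            return t_loss
        neutral_median = np.median(loss_times(False, reps=400, cap=4000))
        horizon = int(10 * neutral_median)
        nfds_losses = loss_times(True, reps=200, cap=horizon)
        assert np.median(nfds_losses) >= horizon  # >=half still segregating


class TestHeterozygosityDecay:
    def test_neutral_decay_rate(self, rng):
        # E[2p(1-p)] shrinks by (1 - 1/2N) per generation without mutation
        n, gens, reps = 50, 40, 3000
        traj = allele_trajectories(0.5, n, gens, reps, rng, record=True)
        het = 2 * traj[-1] * (1 - traj[-1])
        expected = 0.5 * (1 - 1 / (2 * n)) ** gens
        sem = het.std(ddof=1) / np.sqrt(reps)
        assert abs(het.mean() - expected) < 3 * sem


class TestLocusStructure:
    def test_codon_rule_gives_two_to_one(self):
        locus = LocusStructure.single_exon()
        mask = locus.is_nonsynonymous()
        assert mask.sum() == 2 * (~mask).sum()
        assert locus.coding_length == 288

    def test_human_gene_shape(self):
        gene = LocusStructure.human_gene()
        assert gene.n_exons == 9 and gene.n_introns == 8
        assert gene.intron_length == 5419
        assert gene.coding_length == 9 * 288

    def test_balanced_positions_are_nonsynonymous_exon_centres(self):
        gene = LocusStructure.human_gene()
        pos = gene.balanced_positions()
        assert len(pos) == 9
        assert pos[0] == 144
        assert gene.is_nonsynonymous()[pos].all()

    def test_invalid_shapes(self):
        with pytest.raises(ValueError):
            LocusStructure(n_exons=3, n_introns=1)


class TestScenarioConfig:
    def test_duplication_requires_equal_daughters(self):
        with pytest.raises(ValueError):
            ScenarioConfig(mode="duplication", split_fractions=(0.5, 0.5))

    def test_sample_times_must_be_sorted(self):
        with pytest.raises(ValueError):
            ScenarioConfig(sample_times=(1.0, 0.5))

    def test_rescaling_trades_size_for_rates(self):
        cfg = ScenarioConfig(n_ancestral=200, mu=1e-8).rescaled(4)
        assert cfg.n_ancestral == 50
        assert cfg.mu == pytest.approx(4e-8)

    def test_daughter_sizes(self):
        v = ScenarioConfig(mode="vicariance", split_fractions=(0.75, 0.25))
        assert v.daughter_sizes() == (150, 50)
        d = ScenarioConfig(mode="dispersal", split_fractions=(1.0, 0.25))
        assert d.daughter_sizes() == (200, 50)


def _small_config(**kw):
    defaults = dict(n_ancestral=30, mu=2e-4, sample_times=(0.2, 0.5))
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestRunScenario:
    def test_samples_have_valid_frequencies_and_times(self):
        run = run_scenario(_small_config(), LocusStructure.single_exon(), seed=0)
        assert [s.time_n for s in run.samples] == [0.2, 0.5]
        for s in run.samples:
            for arr in (s.freq_pop1, s.freq_pop2):
                assert ((arr >= 0) & (arr <= 1)).all()
            seg = ((s.freq_pop1 > 0) & (s.freq_pop1 < 1)) | (
                (s.freq_pop2 > 0) & (s.freq_pop2 < 1)
            )
            assert seg.all()  # only segregating sites recorded

    def test_balanced_retention_rule(self):
        balanced = BalancedPolyConfig(init_freq=0.2)
        run = run_scenario(
            _small_config(), LocusStructure.single_exon(),
            balanced=balanced, seed=1, max_retries=500,
        )
        assert run.n_discarded >= 0
        for s in run.samples:
            bal = s.is_balanced
            assert bal.any()
            assert s.is_nonsyn[bal].all()  # balanced sites are nonsynonymous
            assert ((s.freq_pop1[bal] > 0) & (s.freq_pop1[bal] < 1)).all()
            assert ((s.freq_pop2[bal] > 0) & (s.freq_pop2[bal] < 1)).all()

    def test_deterministic_under_seed(self):
        r1 = run_scenario(_small_config(), LocusStructure.single_exon(), seed=42)
        r2 = run_scenario(_small_config(), LocusStructure.single_exon(), seed=42)
        for a, b in zip(r1.samples, r2.samples):
            np.testing.assert_array_equal(a.freq_pop1, b.freq_pop1)
            np.testing.assert_array_equal(a.freq_pop2, b.freq_pop2)


class TestClassifySimSites:
    def test_hand_built_sample(self):
        sample = SimSample(
            time_n=1.0,
            positions=np.arange(9),
            freq_pop1=np.array([0.3, 0.4, 0.2, 0.3, 0.1, 0.2, 0.25, 0.3, 0.15]),
            freq_pop2=np.array([0.5, 0.2, 0.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
            is_nonsyn=np.array([1, 1, 0, 1, 1, 1, 0, 0, 0], dtype=bool),
            is_balanced=np.zeros(9, dtype=bool),
        )
        binned = classify_sim_sites(sample)
        t = binned.total
        assert (t.s_n, t.s_s, t.r_n, t.r_s) == (2, 1, 3, 3)

    def test_empty_sample(self):
        sample = SimSample(
            1.0, np.empty(0, int), np.empty(0), np.empty(0),
            np.empty(0, bool), np.empty(0, bool),
        )
        assert classify_sim_sites(sample).total.total == 0


class TestBatch:
    def test_pooled_equals_replicate_sum(self):
        cfg = _small_config()
        batch = run_batch(cfg, LocusStructure.single_exon(), n_replicates=50, seed=3)
        cells, _ = batch.replicate_cells(0)
        binned, _ = batch.pooled_counts(0)
        np.testing.assert_allclose(
            cells.sum(axis=0),
            np.array([[t.s_n, t.s_s, t.r_n, t.r_s] for t in binned.per_bin]),
        )

    def test_batch_agrees_with_scalar_classification(self):
        # the vectorised binning must match the SiteRecord pipeline on one replicate
        cfg = _small_config()
        run = run_scenario(cfg, LocusStructure.single_exon(), seed=9)
        sample = run.samples[0]
        binned = classify_sim_sites(sample, focal="pop1")
        # emulate the batch accumulator on the same arrays
        batch_like = {
            "rep": np.zeros(sample.n_sites, dtype=np.int64),
            "p1": sample.freq_pop1,
            "p2": sample.freq_pop2,
            "is_nonsyn": sample.is_nonsyn,
        }
        from balsel.simulate import BatchResult

        cells = np.zeros((1, 5, 4))
        BatchResult._accumulate(cells, batch_like, "pop1", 0.1, None)
        np.testing.assert_allclose(
            cells[0],
            np.array([[t.s_n, t.s_s, t.r_n, t.r_s] for t in binned.per_bin]),
        )

    def test_migration_increases_sharing(self):
        # the private fraction rho falls monotonically as migration rises
        rhos = []
        for m in (0.0, 0.05, 0.2):
            cfg = _small_config(migration_rate=m, sample_times=(1.0,))
            batch = run_batch(cfg, LocusStructure.single_exon(), n_replicates=150, seed=11)
            binned, _ = batch.pooled_counts(0)
            t = binned.total
            shared = t.s_n + t.s_s
            private = t.r_n + t.r_s
            rhos.append(private / (shared + private))
        assert rhos[0] > rhos[1] > rhos[2]

    def test_balanced_batch_reports_retention(self):
        cfg = _small_config(sample_times=(0.5,))
        batch = run_batch(
            cfg, LocusStructure.single_exon(),
            balanced=BalancedPolyConfig(init_freq=0.3),
            n_replicates=60, seed=5,
        )
        assert batch.n_retained(0) <= batch.n_replicates
        assert batch.n_attempts >= batch.n_replicates
        _, bal = batch.pooled_counts(0)
        assert bal.sum() == batch.n_retained(0)  # one shared balanced site each
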