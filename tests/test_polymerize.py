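import numpy as np
import pytest

from rhpkit.chemistry import DEFAULT_MONOMERS, MonomerSystem, default_system
from rhpkit.polymerize import (SimulationConfig, SimulationError,
                               batch_summary, filter_oligomers,
                               propagation_probs, sample_chain_lengths,
                               simulate_batch)


def binary_system(r12=1.0, r21=1.0, feed=(0.5, 0.5)):
    return MonomerSystem(
        monomers=[DEFAULT_MONOMERS["MMA"], DEFAULT_MONOMERS["OEGMA"]],
        feed_fractions=np.asarray(feed),
        reactivity_ratios=np.array([[1.0, r12], [r21, 1.0]]),
    )


class TestPropagationProbs:
    def test_ideal_ratios_reduce_to_pool_fractions(self, system4):
        p = propagation_probs(0, [50, 25, 20, 5], system4)
        assert p == pytest.approx([0.5, 0.25, 0.20, 0.05])

    def test_terminal_preference_with_unequal_ratios(self):
        # r_12 = 2: radical 1 adds its own kind twice as readily
        s = binary_system(r12=2.0)
        p = propagation_probs(0, [0.5, 0.5], s)
        assert p == pytest.approx([2 / 3, 1 / 3])

    def test_single_monomer_system(self):
        s = MonomerSystem(monomers=[DEFAULT_MONOMERS["MMA"]],
                          feed_fractions=np.array([1.0]))
        assert propagation_probs(0, [10], s) == pytest.approx([1.0])

    def test_depleted_pool_raises(self, system4):
        with pytest.raises(SimulationError):
            propagation_probs(0, [0, 0, 0, 0], system4)


class TestChainLengths:
    def test_monodisperse_limit(self):
        rng = np.random.default_rng(0)
        lengths = sample_chain_lengths(50, 100.0, 1.0, rng)
        assert (lengths == 100).all()

    def test_schulz_zimm_moments(self):
        """PDI ~= 1 + sigma^2/mu^2: dp 100 / PDI 1.2 gives variance ~2000."""
        rng = np.random.default_rng(42)
        lengths = sample_chain_lengths(15000, 100.0, 1.2, rng).astype(float)
        assert lengths.mean() == pytest.approx(100.0, rel=0.02)
        assert lengths.var() == pytest.approx(2000.0, rel=0.08)

    def test_subunity_pdi_rejected(self):
        with pytest.raises(SimulationError):
            sample_chain_lengths(10, 100.0, 0.9, np.random.default_rng(0))


class TestSimulateBatch:
    def test_conversion_realized_exactly(self, default_batch):
        consumed = int(default_batch.consumed.sum())
        pool = int(default_batch.initial_pool.sum())
        assert abs(consumed - 0.5 * pool) <= 1  # within one monomer addition

    def test_mass_conservation_exact(self, default_batch):
        """Units in chains + units left in pool = initial pool, per monomer type."""
        n = default_batch.system.n_monomers
        in_chains = np.zeros(n, dtype=np.int64)
        for c in default_batch.chains:
            in_chains += np.bincount(c.sequence, minlength=n)
        assert (in_chains == default_batch.consumed).all()
        assert (default_batch.consumed <= default_batch.initial_pool).all()

    def test_ideal_batch_mean_composition_matches_feed(self, default_batch):
        from rhpkit.heterogeneity import chain_compositions
        comps = chain_compositions(default_batch)
        assert comps["MMA"].mean() == pytest.approx(0.50, abs=0.005)

    def test_seeded_bit_reproducibility(self, system4):
        cfg = dict(system=system4, nc=100, dp_target=50.0, seed=99)
        a = simulate_batch(SimulationConfig(**cfg))
        b = simulate_batch(SimulationConfig(**cfg))
        assert all((x.sequence == y.sequence).all()
                   for x, y in zip(a.chains, b.chains))
        c = simulate_batch(SimulationConfig(**{**cfg, "seed": 100}))
        assert any(len(x) != len(y) or (x.sequence != y.sequence).any()
                   for x, y in zip(a.chains, c.chains))

    def test_mayo_lewis_copolymer_equation_limit(self):
        """At vanishing conversion the incorporated fraction obeys the
        closed-form copolymer equation: r1=2, r2=0.5, f=(0.5,0.5) -> F1 = 2/3.

        The first unit of each chain is an initiation draw from the bare
        feed, not a propagation event, so it is excluded from the estimate.
        """
        s = binary_system(r12=2.0, r21=0.5)
        cfg = SimulationConfig(system=s, nc=4000, dp_target=100.0,
                               conversion_target=0.01, pdi_target=1.0, seed=7)
        b = simulate_batch(cfg)
        fracs = np.array([(c.sequence[1:] == 0).mean() for c in b.chains])
        f1, f2, r1, r2 = 0.5, 0.5, 2.0, 0.5
        expected = (r1 * f1**2 + f1 * f2) / (r1 * f1**2 + 2 * f1 * f2 + r2 * f2**2)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - expected) < 3 * se + 1e-12

    def test_compositional_drift_depletes_reactive_monomer(self):
        """With r1 > 1 > r2 monomer 1 is consumed first: its residual pool
        fraction decreases as conversion increases."""
        residual = []
        for conv in (0.2, 0.5, 0.8):
            s = binary_system(r12=2.0, r21=0.5)
            cfg = SimulationConfig(system=s, nc=2000, dp_target=50.0,
                                   conversion_target=conv, pdi_target=1.0,
                                   seed=11)
            b = simulate_batch(cfg)
            left = b.initial_pool - b.consumed
            residual.append(left[0] / left.sum())
        assert residual[0] > residual[1] > residual[2]
        assert residual[0] < 0.5  # already depleted relative to feed

    def test_pdi_respects_target(self, default_batch, monodisperse_batch):
        assert batch_summary(default_batch).pdi <= 1.2 + 0.01
        assert batch_summary(monodisperse_batch).pdi == pytest.approx(1.0)


class TestFilterAndSummary:
    def test_oligomer_filter_retains_only_long_chains(self, default_batch):
        filtered = filter_oligomers(default_batch, min_dp=15)
        lengths = filtered.lengths()
        assert lengths.min() >= 15
        expected_removed = int((default_batch.lengths() < 15).sum())
        assert filtered.meta["oligomers_removed"] == expected_removed

    def test_filter_mass_accounting(self, small_batch):
        filtered = filter_oligomers(small_batch, min_dp=15)
        removed = filtered.meta["oligomer_units_removed"]
        assert (small_batch.consumed == filtered.consumed + removed).all()

    def test_min_dp_one_is_identity(self, small_batch):
        filtered = filter_oligomers(small_batch, min_dp=1)
        assert filtered.nc == small_batch.nc

    def test_summary_moments_on_known_lengths(self, system4):
        from rhpkit.batchio import generate_fixture
        b = generate_fixture("fixed_lengths", system4, seed=0,
                             lengths=[50, 150])
        s = batch_summary(b)
        assert s.dp_n == pytest.approx(100.0)
        assert s.dp_w == pytest.approx(125.0)  # (50^2+150^2)/200
        assert s.pdi == pytest.approx(1.25)

    def test_empty_batch_summary_raises(self, system4):
        from rhpkit.polymerize import Batch
        empty = Batch(chains=[], config=SimulationConfig(system=system4),
                      initial_pool=np.zeros(4, dtype=np.int64),
                      consumed=np.zeros(4, dtype=np.int64))
        with pytest.raises(SimulationError):
            batch_summary(empty)
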