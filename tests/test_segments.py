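import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhpkit.batchio import generate_fixture
from rhpkit.chemistry import HYDROPHILIC, HYDROPHOBIC
from rhpkit.polymerize import Chain
from rhpkit.segments import (SegmentError, batch_level_distribution,
                             binarize_chain, find_specific_segments,
                             run_lengths, run_segments,
                             sequence_level_distribution)


def brute_force_runs(labels):
    """Position-by-position oracle for maximal run lengths."""
    true_runs, false_runs = [], []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        (true_runs if labels[i] else false_runs).append(j - i)
        i = j
    return true_runs, false_runs


def chain_of(system, symbols):
    return Chain(np.array([system.index_of(s) for s in symbols]))


class TestBinarize:
    def test_reference_chain(self, system4):
        bc = binarize_chain(chain_of(system4, ["MMA", "OEGMA", "EHMA", "SPMA"]),
                            system4)
        assert bc.label_strings() == [HYDROPHOBIC, HYDROPHILIC,
                                      HYDROPHOBIC, HYDROPHILIC]

    def test_threshold_6_flips_mma(self, system4):
        """At cutoff 6 only EHMA (5.12) stays hydrophobic; MMA (8.45) flips."""
        from rhpkit.chemistry import default_system
        s6 = default_system(hlb_threshold=6.0)
        bc = binarize_chain(chain_of(s6, ["MMA", "EHMA"]), s6)
        assert bc.label_strings() == [HYDROPHILIC, HYDROPHOBIC]


class TestRunSegments:
    def test_hand_worked_runs(self, system4):
        bc = binarize_chain(
            chain_of(system4, ["MMA", "MMA", "OEGMA", "MMA", "MMA", "MMA"]),
            system4)
        runs = run_segments(bc)
        assert runs[HYDROPHOBIC] == [2, 3]
        assert runs[HYDROPHILIC] == [1]

    def test_uniform_and_alternating(self, system4):
        uniform = binarize_chain(chain_of(system4, ["MMA"] * 7), system4)
        assert run_segments(uniform)[HYDROPHOBIC] == [7]
        alt = binarize_chain(chain_of(system4, ["MMA", "OEGMA"] * 3), system4)
        assert run_segments(alt)[HYDROPHOBIC] == [1, 1, 1]
        assert run_segments(alt)[HYDROPHILIC] == [1, 1, 1]

    def test_against_bruteforce_oracle_on_random_strings(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            labels = rng.random(rng.integers(1, 201)) < rng.random()
            assert run_lengths(labels) == brute_force_runs(labels.tolist())

    @given(st.lists(st.booleans(), max_size=100))
    @settings(deadline=None, derandomize=True)
    def test_run_lengths_cover_every_position(self, labels):
        t, f = run_lengths(np.array(labels, dtype=bool))
        assert sum(t) + sum(f) == len(labels)
        assert all(l >= 1 for l in t + f)


class TestDistributions:
    def test_sequence_level_averages_per_chain(self, system4):
        # chains with phobic runs [1, 3] and [3]
        b = generate_fixture("handcrafted", system4, sequences=[
            ["MMA", "OEGMA", "MMA", "MMA", "MMA"],
            ["OEGMA", "MMA", "MMA", "MMA"],
        ])
        d = sequence_level_distribution(b, HYDROPHOBIC)
        assert d.get(1) == pytest.approx(0.5)
        assert d.get(3) == pytest.approx(1.0)

    def test_batch_level_is_sequence_level_times_nc(self, small_batch):
        seq = sequence_level_distribution(small_batch, HYDROPHOBIC)
        bat = batch_level_distribution(small_batch, HYDROPHOBIC)
        for l, v in bat.values.items():
            assert v == pytest.approx(seq.get(l) * small_batch.nc)

    def test_length_weighted_counts_conserve_units(self, small_batch):
        total = 0.0
        for cls in (HYDROPHOBIC, HYDROPHILIC):
            d = batch_level_distribution(small_batch, cls)
            total += sum(l * v for l, v in d.values.items())
        assert total == int(small_batch.lengths().sum())

    def test_geometric_run_law_on_bernoulli_chains(self, system4):
        """i.i.d. draws with hydrophobic probability p produce geometric
        interior phobic runs: P(L = l) = p^(l-1) (1 - p)."""
        from scipy import stats
        p = 0.7  # MMA + EHMA feed
        L, kmax = 100, 12
        b = generate_fixture("bernoulli", system4, seed=15, nc=5500, length=L)
        # Unbiased sampling: only runs starting at least kmax positions from
        # the omega end, with lengths >= kmax pooled into the tail bin, avoid
        # the length-biased censoring of end-clipped runs.
        binned = []
        for c in b.chains:
            ph = system4.hlb_values[c.sequence] < 9.0
            starts = np.flatnonzero(ph[1:] & ~ph[:-1]) + 1
            starts = starts[starts <= L - kmax]
            philic_pos = np.flatnonzero(~ph)
            nxt = np.searchsorted(philic_pos, starts)
            ends = np.where(nxt < philic_pos.size,
                            philic_pos[np.minimum(nxt, philic_pos.size - 1)], L)
            binned.extend(np.minimum(ends - starts, kmax).tolist())
        binned = np.array(binned)
        assert binned.size > 1e5
        observed = np.array([(binned == k).sum() for k in range(1, kmax + 1)],
                            dtype=float)
        probs = np.array([p ** (k - 1) * (1 - p) for k in range(1, kmax)]
                         + [p ** (kmax - 1)])
        chi2, pval = stats.chisquare(observed, probs * binned.size)
        assert pval > 1e-3


class TestMotifSearch:
    @pytest.mark.parametrize(
        "symbols, n_matches, length",
        [
            (["MMA", "MMA", "OEGMA", "MMA", "MMA"], 1, 5),
            (["MMA", "OEGMA", "MMA", "MMA"], 0, None),          # marker 1 from end
            (["MMA", "MMA", "OEGMA", "OEGMA", "MMA", "MMA"], 0, None),  # 2 markers
            (["EHMA", "MMA", "OEGMA", "MMA", "EHMA", "MMA"], 1, 6),
        ],
    )
    def test_embedded_marker_rule(self, system4, symbols, n_matches, length):
        b = generate_fixture("handcrafted", system4, sequences=[symbols])
        dist, matches = find_specific_segments(b, marker="OEGMA", end_gap=2)
        assert len(matches) == n_matches
        if n_matches:
            assert matches[0].length == length

    def test_match_terminated_by_hydrophilic_monomer(self, system4):
        # SPMA breaks the run: marker ends up 1 from the run end -> no match
        b = generate_fixture("handcrafted", system4, sequences=[
            ["MMA", "MMA", "OEGMA", "MMA", "SPMA", "MMA"]])
        _, matches = find_specific_segments(b)
        assert matches == []

    def test_matches_lie_in_disjoint_runs(self, default_batch):
        """Every match is a maximal phobic-or-marker run; matches never overlap."""
        _, matches = find_specific_segments(default_batch)
        assert len(matches) > 0
        by_chain = {}
        for m in matches:
            by_chain.setdefault(m.chain, []).append(m)
        system = default_batch.system
        allowed_mask = (system.hlb_values < 9.0)
        marker = system.index_of("OEGMA")
        for ci, ms in by_chain.items():
            seq = default_batch.chains[ci].sequence
            ms = sorted(ms, key=lambda m: m.start)
            for a, b_ in zip(ms, ms[1:]):
                assert a.end <= b_.start
            for m in ms:
                run = seq[m.start:m.end]
                assert ((allowed_mask[run]) | (run == marker)).all()
                assert (run == marker).sum() == 1
                # maximality: flanked by disallowed positions or chain ends
                if m.start > 0:
                    prev = seq[m.start - 1]
                    assert not (allowed_mask[prev] or prev == marker)
                if m.end < seq.size:
                    nxt = seq[m.end]
                    assert not (allowed_mask[nxt] or nxt == marker)

    def test_unknown_marker_raises(self, small_batch):
        from rhpkit.chemistry import ChemistryError
        with pytest.raises((SegmentError, ChemistryError)):
            find_specific_segments(small_batch, marker="NOPE")
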