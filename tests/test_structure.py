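import math

import numpy as np
import pytest

from mirsite import (
    TranscriptRecord,
    accessibility_profile,
    block_accessibility,
    delta_g_disruption,
    delta_g_nucl,
    delta_g_total,
    fold_sequence,
    fold_window,
)
from mirsite.duplex import HybridDuplex
from mirsite.structure import EnsembleModel
from oracles import enumerate_ensemble


def rand_rna(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


def fake_ensemble(s, seq=None, offset=0):
    s = np.asarray(s, dtype=float)
    n = len(s)
    return EnsembleModel(seq or "A" * n, offset, np.zeros((n, n)), s, 0.0)


class TestFoldSequence:
    def test_unpairable_sequence_is_fully_open(self):
        ens = fold_sequence("AAAAAAAAAA")
        assert ens.e_ens == 0.0
        assert np.allclose(ens.s, 1.0)
        assert np.allclose(ens.p, 0.0)

    def test_matches_enumeration(self, params):
        rng = np.random.default_rng(9)
        for _ in range(12):
            seq = rand_rna(rng, int(rng.integers(6, 19)))
            _, e, p, s = enumerate_ensemble(seq, params)
            ens = fold_sequence(seq, params)
            assert ens.e_ens == pytest.approx(e, abs=1e-9)
            assert np.allclose(ens.p, p, atol=1e-9)
            assert np.allclose(ens.s, s, atol=1e-9)

    def test_hairpin_loop_more_accessible_than_stem(self):
        ens = fold_sequence("GGGGAAAACCCC")
        loop = ens.s[4:8].mean()
        stem = np.r_[ens.s[:4], ens.s[8:]].mean()
        assert loop > stem

    def test_short_window_fully_single_stranded(self):
        ens = fold_sequence("GCG")
        assert np.allclose(ens.s, 1.0)
        assert ens.e_ens == 0.0


class TestAccessibility:
    def test_block_mean_arithmetic(self):
        ens = fake_ensemble([0.2, 0.4, 1.0])
        assert block_accessibility(ens, 0, 2) == pytest.approx(0.3)
        assert block_accessibility(ens, 2, 3) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            block_accessibility(ens, 2, 2)

    def test_unstructured_transcript_all_ones(self):
        tx = TranscriptRecord("t", "A" * 80)
        ens = fold_window(tx, (30, 50), 80)
        prof = accessibility_profile(tx, (30, 50), ens, (5, 10))
        assert prof.site_access == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in prof.upstream_access.values())
        assert all(v == pytest.approx(1.0) for v in prof.downstream_access.values())

    def test_site_at_edge_has_missing_upstream(self):
        tx = TranscriptRecord("t", "A" * 60)
        ens = fold_window(tx, (0, 20), 60)
        prof = accessibility_profile(tx, (0, 20), ens, (5, 10))
        assert all(math.isnan(v) for v in prof.upstream_access.values())
        assert all(not math.isnan(v) for v in prof.downstream_access.values())

    def test_stem_site_less_accessible_than_open_flank(self):
        # hairpin: stem arms GGGGGG/CCCCCC, open A-flanks on both sides
        seq = "A" * 10 + "GGGGGG" + "AAAA" + "CCCCCC" + "A" * 10
        tx = TranscriptRecord("t", seq)
        ens = fold_window(tx, (10, 16), len(seq))
        site = block_accessibility(ens, 10, 16)
        flank = block_accessibility(ens, 0, 10)
        assert site < 0.5 < flank


class TestDisruption:
    def test_unstructured_window_costs_nothing(self):
        tx = TranscriptRecord("t", "A" * 100)
        assert delta_g_disruption(tx, (40, 60)) == 0.0

    def test_matches_constrained_enumeration(self, params):
        rng = np.random.default_rng(21)
        for _ in range(6):
            seq = rand_rna(rng, 16)
            tx = TranscriptRecord("t", seq)
            a, b = 5, 9
            _, e_free, _, _ = enumerate_ensemble(seq, params)
            _, e_con, _, _ = enumerate_ensemble(
                seq, params, banned=frozenset(range(a, b))
            )
            got = delta_g_disruption(tx, (a, b), window_size=len(seq), params=params)
            assert got == pytest.approx(max(e_con - e_free, 0.0), abs=1e-9)

    def test_nonnegative_on_random_sequences(self, params):
        rng = np.random.default_rng(33)
        for _ in range(15):
            seq = rand_rna(rng, 60)
            tx = TranscriptRecord("t", seq)
            assert delta_g_disruption(tx, (20, 35), 60, params) >= 0.0

    def test_total_energy_identities(self):
        assert delta_g_total(-20.0, 0.0) == -20.0
        assert delta_g_total(-20.0, 5.0) == -15.0


class TestNucleation:
    def _duplex(self, n_pairs, t_hi=9):
        pairs = tuple((k, t_hi - k) for k in range(n_pairs))
        return HybridDuplex("m", "t", t_hi - n_pairs + 1, t_hi + 1, pairs, -9.0)

    def test_fully_accessible_equals_helix_energy(self, params):
        d = self._duplex(4)
        ens = fake_ensemble(np.ones(12))
        got = delta_g_nucl(d, ens, "GGGG", "A" * 6 + "CCCC" + "AA", params)
        want = params.duplex_init + 3 * params.stack[4 * 2 + 1, 4 * 2 + 1]
        assert got == pytest.approx(want, abs=1e-12)

    def test_short_run_has_no_nucleation(self, params):
        d = self._duplex(3)
        ens = fake_ensemble(np.ones(12))
        assert math.isnan(
            delta_g_nucl(d, ens, "GGGG", "A" * 7 + "CCC" + "AA", params)
        )

    def test_prefers_accessible_block(self, params):
        # 5 stacked GC pairs -> two 4-pair blocks of equal helix energy;
        # the 3'-target block is fully open, the 5' one half closed
        d = self._duplex(5, t_hi=9)
        s = np.ones(12)
        s[5] = 0.2            # depress the block using target position 5
        ens = fake_ensemble(s)
        got = delta_g_nucl(d, ens, "GGGGG", "A" * 5 + "CCCCC" + "AA", params)
        helix = params.duplex_init + 3 * params.stack[4 * 2 + 1, 4 * 2 + 1]
        assert got == pytest.approx(helix, abs=1e-12)   # open block wins

    def test_unfavorable_block_reports_no_nucleation(self, params):
        # AU-only 4-helix: initiation outweighs the stacks
        d = self._duplex(4)
        ens = fake_ensemble(np.ones(12))
        got = delta_g_nucl(d, ens, "AAAA", "A" * 6 + "UUUU" + "AA", params)
        assert math.isnan(got)


class TestSampling:
    def test_sample_frequencies_match_exact_ensemble(self, params):
        from mirsite.structure import sample_structures
        from oracles import structure_energy
        from mirsite.params import encode
        import math

        seq = "GGCAAAAGCCAUAUGG"
        ens = fold_sequence(seq, params)
        samples = sample_structures(seq, 4000, seed=5, params=params)
        # empirical single-strandedness tracks the exact profile
        n = len(seq)
        s_emp = np.ones(n)
        for pairs in samples:
            for i, j in pairs:
                s_emp[i] -= 1 / len(samples)
                s_emp[j] -= 1 / len(samples)
        assert np.abs(s_emp - ens.s).max() < 0.05
        # per-structure empirical frequency tracks its Boltzmann weight
        codes = encode(seq)
        from collections import Counter
        counts = Counter(samples)
        top, freq = counts.most_common(1)[0]
        z = math.exp(-ens.e_ens / params.rt)
        p_top = math.exp(-structure_energy(codes, list(top), params)
                         / params.rt) / z
        assert freq / len(samples) == pytest.approx(p_top, abs=0.04)

    def test_sampling_deterministic_given_seed(self, params):
        from mirsite.structure import sample_structures
        seq = "GGCGAAAACGCC"
        a = sample_structures(seq, 50, seed=9, params=params)
        b = sample_structures(seq, 50, seed=9, params=params)
        assert a == b


class TestWindowStability:
    def test_block_accessibility_stable_under_window_extension(self, params):
        # a hairpin flanked by unpairable poly-A: widening the window far
        # beyond the pairing span must not move the block accessibility
        core = "GGGGGG" + "AAAA" + "CCCCCC"
        seq = "A" * 60 + core + "A" * 60
        tx = TranscriptRecord("t", seq)
        site = (60, 60 + len(core))
        vals = []
        for w in (40, 80, 120):
            ens = fold_window(tx, site, w, params)
            vals.append(block_accessibility(ens, 62, 66))
        assert max(vals) - min(vals) < 1e-9
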