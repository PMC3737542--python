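import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirsite import (
    MiRnaRecord,
    TranscriptRecord,
    classify_seed,
    dedup_overlapping,
    duplex_energy,
    scan_candidate_sites,
    three_prime_pairing,
)
from mirsite.duplex import CandidateSite, HybridDuplex, SeedType
from mirsite.synth import revcomp

from oracles import enumerate_duplex_min, seed_truth_table

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def rand_rna(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


def make_duplex(pairs, target_start=None, target_end=None, dg=-10.0):
    tj = [j for _, j in pairs]
    return HybridDuplex(
        "m", "t",
        min(tj) if target_start is None else target_start,
        max(tj) + 1 if target_end is None else target_end,
        tuple(sorted(pairs)), dg,
    )


class TestDuplexEnergy:
    def test_perfect_helix_manual_sum(self, params):
        # 4 GG/CC stacks plus initiation, summed by hand from the table
        d = duplex_energy("GGGGG", "CCCCC", params=params)
        expected = 4 * params.stack[4 * 2 + 1, 4 * 2 + 1] + params.duplex_init
        assert d.dg_hybrid == pytest.approx(expected, abs=1e-12)
        assert len(d.pairs) == 5

    def test_no_pairable_bases(self):
        assert duplex_energy("AAAA", "AAAA") is None

    def test_matches_exhaustive_enumeration(self, params):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(40):
            m = rand_rna(rng, int(rng.integers(4, 11)))
            t = rand_rna(rng, int(rng.integers(4, 11)))
            oracle = enumerate_duplex_min(m, t, params)
            d = duplex_energy(m, t, params=params)
            if oracle is None:
                assert d is None
            else:
                assert d.dg_hybrid == pytest.approx(oracle, abs=1e-9)
                checked += 1
        assert checked > 10

    def test_seed_forcing_never_beats_unconstrained(self, params):
        rng = np.random.default_rng(7)
        seen = 0
        for _ in range(30):
            m = rand_rna(rng, 22)
            # guarantee an anchor by planting the seed complement
            t = rand_rna(rng, 10) + revcomp(m[1:7]) + rand_rna(rng, 10)
            forced = duplex_energy(m, t, forced_seed_span=(1, 7), params=params)
            assert forced is not None
            free = duplex_energy(m, t, params=params)
            assert free is not None
            assert forced.dg_hybrid >= free.dg_hybrid - 1e-9
            seen += 1
        assert seen == 30

    def test_pairing_map_is_monotone(self, params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = duplex_energy(rand_rna(rng, 15), rand_rna(rng, 25), params=params)
            if d is None:
                continue
            mis = [p[0] for p in d.pairs]
            tjs = [p[1] for p in d.pairs]
            assert mis == sorted(mis)
            assert tjs == sorted(tjs, reverse=True)


class TestClassifySeed:
    def _site(self, mirna, opposite1="A", break_nt=None):
        """Target with the complement of miRNA nt 1-8, mutated as asked."""
        block = list(revcomp(mirna[:8]))
        block[-1] = opposite1
        if break_nt is not None:
            block[8 - break_nt] = "A" if mirna[break_nt - 1] not in "U" else "C"
        target = "GG" + "".join(block) + "GG"
        pairs = []
        for mi in range(1, 8):
            j = 2 + (8 - 1 - mi)
            if break_nt is not None and mi == break_nt - 1:
                continue
            pairs.append((mi, j))
        return make_duplex(pairs), mirna, target

    def test_definition_cases(self):
        d, m, t = self._site(LET7, opposite1="A")
        assert classify_seed(d, m, t) is SeedType.EIGHT_MER
        d, m, t = self._site(LET7, opposite1="G")
        assert classify_seed(d, m, t) is SeedType.SEVEN_MER_M8

    def test_six_mer_with_mismatched_nt8(self):
        # WC at nt 2-7, nt 8 mismatch, G opposite nt 1 -> 6mer
        block = list(revcomp(LET7[:8]))
        block[-1] = "G"       # opposite nt 1: not A
        block[0] = "C"        # opposite nt 8 (G): C pairs... use A instead
        block[0] = "A"
        target = "GG" + "".join(block) + "GG"
        pairs = [(mi, 2 + 7 - mi) for mi in range(1, 7)]
        assert classify_seed(make_duplex(pairs), LET7, target) is SeedType.SIX_MER

    def test_gu_in_seed_demotes_to_seedless(self):
        # nt 4 of let-7 is G; a U opposite it is a GU pair, not WC
        block = list(revcomp(LET7[:8]))
        block[8 - 4] = "U"
        target = "GG" + "".join(block) + "GG"
        pairs = [(mi, 2 + 7 - mi) for mi in range(1, 8)]
        assert classify_seed(make_duplex(pairs), LET7, target) is SeedType.SEEDLESS

    def test_agrees_with_truth_table_on_random_panel(self):
        rng = np.random.default_rng(123)
        classes = set()
        for _ in range(500):
            mirna = rand_rna(rng, 22)
            # complement-derived target block with random point mutations,
            # so WC spans of every length (and GU demotions) occur
            block = list(revcomp(mirna[:9]))
            for k in range(9):
                if rng.random() < 0.25:
                    block[k] = "ACGU"[int(rng.integers(4))]
            target = "GG" + "".join(block) + "GG"
            pairs = []
            j = 2 + 8           # position opposite miRNA nt 1
            for mi in range(0, 9):
                if rng.random() < 0.9:
                    pairs.append((mi, j - mi))
            if rng.random() < 0.15 and len(pairs) > 2:
                k = int(rng.integers(1, len(pairs)))
                pairs = pairs[:k] + [(mi, j - 1) for mi, j in pairs[k:]]
            d = make_duplex(pairs)
            got = classify_seed(d, mirna, target).value
            want = seed_truth_table(dict(pairs), mirna, target)
            assert got == want
            classes.add(got)
        assert classes == {
            "8mer", "7mer-m8", "7mer-A1", "6mer", "offset-6mer", "seedless"
        }


class TestThreePrimePairing:
    def test_contiguous_block_true(self):
        pairs = [(mi, 30 - mi) for mi in range(11, 17)]
        assert three_prime_pairing(
            make_duplex(pairs), LET7, "A" * 40
        ) is False  # A*40 cannot WC-pair any base of let-7 at 12-17

    def test_true_on_real_complement(self):
        target = "CC" + revcomp(LET7[11:17]) + "CC"
        pairs = [(11 + k, 2 + 5 - k) for k in range(6)]
        assert three_prime_pairing(make_duplex(pairs), LET7, target) is True

    def test_bulge_inside_block_false(self):
        target = "CC" + revcomp(LET7[11:17]) + "CC"
        pairs = [(11 + k, 2 + 5 - k) for k in range(6)]
        pairs[3] = (pairs[3][0], pairs[3][1] - 1)   # break target adjacency
        assert three_prime_pairing(make_duplex(pairs), LET7, target) is False

    def test_short_mirna_false_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert three_prime_pairing(
                make_duplex([(1, 5)]), "ACGUACGUACGU", "ACGUACGU"
            ) is False
        assert "17" in caplog.text


class TestScan:
    def test_perfect_complement_found(self, params, config):
        rng = np.random.default_rng(5)
        mir = MiRnaRecord("m", LET7)
        insert = revcomp(LET7)
        seq = rand_rna(rng, 60) + insert + rand_rna(rng, 60)
        tx = TranscriptRecord("t", seq)
        sites = dedup_overlapping(scan_candidate_sites(mir, tx, params, config))
        hits = [s for s in sites if s.start <= 60 + 2 and s.end >= 60 + 20]
        assert hits
        best = min(hits, key=lambda s: s.duplex.dg_hybrid)
        assert best.duplex.dg_hybrid < -25
        # full complement pairs nt 2-8 WC; opposite nt 1 is comp(U) = A
        assert best.seed_type is SeedType.EIGHT_MER

    def test_poly_a_yields_nothing(self):
        sites = scan_candidate_sites(
            MiRnaRecord("m", "A" * 22), TranscriptRecord("t", "A" * 100)
        )
        assert sites == []

    def test_weak_seed_match_found_without_threshold(self, params, config):
        mir = MiRnaRecord("m", "CCACCAACCACCACCACCACCA")
        block = revcomp(mir.seq[1:7])
        tx = TranscriptRecord("t", "A" * 50 + block + "A" * 50)
        sites = scan_candidate_sites(mir, tx, params, config)
        assert len(sites) == 1
        (site,) = sites
        assert site.discovery_mode == "seed-forced"
        assert site.duplex.dg_hybrid > config.dg_threshold  # too weak for mode 1
        assert site.start == 50 and site.end == 56


class TestDedup:
    def _sites(self, spec):
        out = []
        for start, end, st, dg in spec:
            d = HybridDuplex("m", "t", start, end, ((1, start),), dg)
            out.append(CandidateSite(d, st, "3UTR", False, "threshold"))
        return out

    def test_hierarchy_beats_energy(self):
        sites = self._sites([
            (10, 30, SeedType.EIGHT_MER, -16.0),
            (20, 40, SeedType.SEVEN_MER_A1, -18.0),
        ])
        (kept,) = dedup_overlapping(sites)
        assert kept.seed_type is SeedType.EIGHT_MER

    def test_tie_broken_by_lower_dg(self):
        sites = self._sites([
            (10, 30, SeedType.SEVEN_MER_M8, -15.0),
            (20, 40, SeedType.SEVEN_MER_M8, -17.0),
        ])
        (kept,) = dedup_overlapping(sites)
        assert kept.duplex.dg_hybrid == -17.0

    def test_non_overlapping_all_kept(self):
        sites = self._sites([
            (10, 30, SeedType.SIX_MER, -10.0),
            (30, 50, SeedType.EIGHT_MER, -12.0),
        ])
        assert len(dedup_overlapping(sites)) == 2

    @given(st.permutations(range(5)))
    def test_order_invariant_and_idempotent(self, perm):
        base = self._sites([
            (10, 30, SeedType.EIGHT_MER, -16.0),
            (25, 45, SeedType.EIGHT_MER, -19.0),
            (44, 60, SeedType.SIX_MER, -11.0),
            (100, 120, SeedType.SEEDLESS, -22.0),
            (115, 130, SeedType.SEVEN_MER_A1, -9.0),
        ])
        shuffled = [base[i] for i in perm]
        out = dedup_overlapping(shuffled)
        ref = dedup_overlapping(base)
        assert [(s.start, s.end) for s in out] == [(s.start, s.end) for s in ref]
        assert dedup_overlapping(out) == out
        # survivors never overlap
        spans = sorted((s.start, s.end) for s in out)
        assert all(b1 <= a2 for (_, b1), (a2, _) in zip(spans, spans[1:]))
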