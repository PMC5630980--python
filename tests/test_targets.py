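"""Duplex scoring, the two filter profiles, consensus, plant mode."""

import itertools

import numpy as np
import pytest

from lncmir import targets
from lncmir.hairpin import revcomp


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


MIR = "ACGGATTCGAAGGCATTCGAAC"  # 22 nt


class TestDuplexAlign:
    def test_perfect_complement_score(self):
        # 7 seed positions x (5*4) + 15 positions x 5 = 215
        score, site = targets.duplex_align(MIR, revcomp(MIR))
        assert score == 215.0
        assert site == (0, 22)

    def test_empty_overlap_scores_zero(self):
        score, site = targets.duplex_align("A" * 22, "A" * 30)
        assert score == 0.0 and site == (0, 0)

    def test_random_targets_rarely_reach_140(self):
        rng = np.random.default_rng(0)
        high = sum(
            targets.duplex_align(MIR, _rand_seq(rng, 22))[0] >= 140 for _ in range(100)
        )
        assert high <= 1  # >= 99/100 below the profile-B score gate

    def test_site_localization(self):
        rng = np.random.default_rng(1)
        host = _rand_seq(rng, 300)
        target = host[:137] + revcomp(MIR) + host[137:]
        score, site = targets.duplex_align(MIR, target)
        assert score == 215.0
        assert site == (137, 159)

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            targets.duplex_align(MIR, "ACGT")

    def test_mirna_length_validated(self):
        with pytest.raises(ValueError):
            targets.duplex_align("ACGT" * 2, "ACGT" * 10)


def _oracle_duplex_energy(a_seq: str, b_seq: str) -> float:
    """Exhaustive enumeration of monotone pairings (tiny inputs only)."""
    a = targets._encode(a_seq)
    c = targets._encode(b_seq[::-1].upper().replace("U", "T"))
    n, m = len(a), len(c)
    cat = targets._PAIR_CAT[a[:, None], c[None, :]]
    best = [0.0]

    def extend(i, j, energy):
        best[0] = min(best[0], energy)
        for di in range(1, targets._MAX_LOOP + 2):
            for dj in range(1, targets._MAX_LOOP + 2):
                ni, nj = i + di, j + dj
                if ni >= n or nj >= m or cat[ni, nj] == 0:
                    continue
                if di == 1 and dj == 1:
                    step = targets._STACK[cat[i, j], cat[ni, nj]]
                elif (di - 1) + (dj - 1) <= targets._MAX_LOOP:
                    step = targets._LOOP_BASE + targets._LOOP_PER_NT * (di + dj - 2)
                else:
                    continue
                extend(ni, nj, energy + step)

    for i in range(n):
        for j in range(m):
            if cat[i, j] > 0:
                extend(i, j, 0.0)
    return best[0]


class TestDuplexEnergy:
    def test_no_complement_is_zero(self):
        assert targets.duplex_energy("A" * 22, "AAACCCAAACCC") == 0.0

    def test_gc_rich_20mer_below_minus_25(self):
        rng = np.random.default_rng(2)
        mir = "".join(rng.choice(list("GC"), size=20))
        assert targets.duplex_energy(mir, revcomp(mir)) <= -25.0

    def test_strand_swap_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = _rand_seq(rng, 20), _rand_seq(rng, 20)
            assert targets.duplex_energy(a, b) == pytest.approx(
                targets.duplex_energy(b, a)
            )

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            a = _rand_seq(rng, int(rng.integers(5, 9)))
            b = _rand_seq(rng, int(rng.integers(5, 9)))
            assert targets.duplex_energy(a, b) == pytest.approx(
                _oracle_duplex_energy(a, b)
            )

    def test_energy_never_positive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            e = targets.duplex_energy(_rand_seq(rng, 22), _rand_seq(rng, 40))
            assert e <= 0.0


class TestProfileGates:
    def test_profile_a_boundary(self):
        assert targets.passes_profile_a(-25.0)
        assert not targets.passes_profile_a(-24.9)

    def test_profile_b_boundaries(self):
        assert targets.passes_profile_b(150.0, -30.0)
        assert not targets.passes_profile_b(150.0, -20.0)  # energy gate
        assert not targets.passes_profile_b(139.0, -30.0)  # score gate
        assert targets.passes_profile_b(140.0, -25.0)  # both inclusive


class TestScans:
    def _planted_targets(self, rng, n_targets=8, n_planted=3):
        tgts, planted = {}, set()
        for i in range(n_targets):
            tid = f"t{i}"
            seq = _rand_seq(rng, 180)
            if i < n_planted:
                pos = int(rng.integers(0, len(seq) - 22))
                seq = seq[:pos] + revcomp(MIR) + seq[pos + 22:]
                planted.add(tid)
            tgts[tid] = seq
        return tgts, planted

    def test_planted_sites_hit_by_both_profiles(self):
        rng = np.random.default_rng(6)
        tgts, planted = self._planted_targets(rng)
        hits_a = targets.scan_profile_a({"mir": MIR}, tgts)
        hits_b = targets.scan_profile_b({"mir": MIR}, tgts)
        assert planted <= {h.target_id for h in hits_a}
        assert planted <= {h.target_id for h in hits_b}
        pairs = targets.consensus(hits_a, hits_b)
        assert planted <= {p.target_id for p in pairs}

    def test_profile_a_site_matches_window_enumeration(self):
        # full-target scan must equal the best windowed energy
        rng = np.random.default_rng(7)
        tgts, _ = self._planted_targets(rng, n_targets=4, n_planted=1)
        for tid, tseq in tgts.items():
            full, _ = targets._duplex_best(MIR, tseq)
            width = len(MIR) + targets._MAX_LOOP * 2
            windowed = min(
                (
                    targets.duplex_energy(MIR, tseq[s : s + width])
                    for s in range(0, len(tseq) - 10)
                ),
                default=0.0,
            )
            assert full == pytest.approx(windowed)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        tgts, _ = self._planted_targets(rng, n_targets=12, n_planted=4)
        mirs = {"mir": MIR}
        prev_a = None
        for emax in (-20.0, -25.0, -30.0, -40.0):
            n = len(targets.scan_profile_a(mirs, tgts, mfe_max=emax))
            if prev_a is not None:
                assert n <= prev_a
            prev_a = n
        prev_b = None
        for smin in (100.0, 140.0, 180.0, 220.0):
            n = len(targets.scan_profile_b(mirs, tgts, score_min=smin))
            if prev_b is not None:
                assert n <= prev_b
            prev_b = n

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            targets.scan_profile_a({"mir": MIR}, {})


class TestConsensus:
    def _hit(self, m, t, profile):
        return targets.DuplexHit(m, t, "mRNA", 0, 22, 150.0, -30.0, profile)

    def test_pairwise_intersection(self):
        a = [self._hit("m1", "t1", "A"), self._hit("m1", "t2", "A")]
        b = [self._hit("m1", "t2", "B")]
        pairs = targets.consensus(a, b)
        assert [(p.mirna_id, p.target_id) for p in pairs] == [("m1", "t2")]

    def test_disjoint_lists_empty(self):
        assert targets.consensus([self._hit("m1", "t1", "A")], [self._hit("m2", "t2", "B")]) == []

    def test_random_oracle(self):
        rng = np.random.default_rng(9)
        mk = lambda: {
            (f"m{rng.integers(4)}", f"t{rng.integers(10)}") for _ in range(25)
        }
        pa, pb = mk(), mk()
        a = [self._hit(m, t, "A") for m, t in pa]
        b = [self._hit(m, t, "B") for m, t in pb]
        got = {(p.mirna_id, p.target_id) for p in targets.consensus(a, b)}
        assert got == pa & pb

    def test_consensus_subset_invariant(self):
        rng = np.random.default_rng(10)
        a = [self._hit(f"m{i%3}", f"t{rng.integers(8)}", "A") for i in range(20)]
        b = [self._hit(f"m{i%3}", f"t{rng.integers(8)}", "B") for i in range(20)]
        pairs = targets.consensus(a, b)
        pa = {(h.mirna_id, h.target_id) for h in a}
        pb = {(h.mirna_id, h.target_id) for h in b}
        got = {(p.mirna_id, p.target_id) for p in pairs}
        assert got <= pa and got <= pb
        assert len(got) <= min(len(pa), len(pb))

    def test_deduplicated(self):
        a = [self._hit("m1", "t1", "A"), self._hit("m1", "t1", "A")]
        b = [self._hit("m1", "t1", "B")]
        assert len(targets.consensus(a, b)) == 1


class TestPlantMode:
    def test_perfect_complement_expectation_zero(self):
        assert targets.plant_expectation(MIR, revcomp(MIR)) == 0.0
        hits = targets.plant_mode_scan({"mir": MIR}, {"cds": revcomp(MIR)})
        assert len(hits) == 1 and hits[0].score == 0.0

    def test_one_seed_mismatch_costs_two(self):
        site = list(revcomp(MIR))
        # miRNA position 4 (1-based) pairs reversed-site index 3 from the end
        pos = len(site) - 1 - 3
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}  # breaks pairing, no G:U
        site[pos] = bad[site[pos]]
        assert targets.plant_expectation(MIR, "".join(site)) == 2.0

    def test_above_cutoff_rejected(self):
        site = list(revcomp(MIR))
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}
        # one seed mismatch (2.0) + two non-seed mismatches (1.0 each) = 4.0
        for mir_pos in (3, 15, 18):
            idx = len(site) - 1 - mir_pos
            site[idx] = bad[site[idx]]
        e = targets.plant_expectation(MIR, "".join(site))
        assert e == 4.0
        hits = targets.plant_mode_scan({"mir": MIR}, {"cds": "".join(site)})
        assert hits == []

    def test_cutoff_inclusive(self):
        site = list(revcomp(MIR))
        bad = {"A": "C", "C": "A", "G": "A", "T": "C"}
        for mir_pos in (15, 17, 19):  # three non-seed mismatches = 3.0
            idx = len(site) - 1 - mir_pos
            site[idx] = bad[site[idx]]
        assert targets.plant_expectation(MIR, "".join(site)) == 3.0
        hits = targets.plant_mode_scan({"mir": MIR}, {"cds": "".join(site)})
        assert len(hits) == 1


class TestHitsIO:
    def test_frame_roundtrip(self):
        hits = [
            targets.DuplexHit("m1", "t1", "mRNA", 5, 27, 180.0, -33.5, "B"),
            targets.DuplexHit("m2", "t2", "lncRNA", 0, 22, 150.0, -28.0, "B"),
        ]
        back = targets.frame_to_hits(targets.hits_to_frame(hits))
        assert back == hits
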