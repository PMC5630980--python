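"""miRNA scanning, folding, star inference and hairpin validation."""

import numpy as np
import pytest

from lncmir import hairpin, simulate


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMirbaseNames:
    @pytest.mark.parametrize(
        "header,family",
        [
            ("cci-miR-281-2-5p", "miR-281"),
            ("dme-bantam-3p", "bantam"),
            ("ame-miR-8", "miR-8"),
            ("hsa-let-7a-5p", "let-7"),
        ],
    )
    def test_family(self, header, family):
        _, fam = hairpin.parse_mirbase_name(header)
        assert fam == family


class TestScanMature:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.mature = _rand_seq(self.rng, 22)

    def _host(self, insert, pos=100):
        host = _rand_seq(self.rng, 300)
        return host[:pos] + insert + host[pos + len(insert):]

    def test_exact_copy_found_at_coordinate(self):
        seq = self._host(self.mature)
        hits = hairpin.scan_mature({"t": seq}, {"m": self.mature})
        sense = [h for h in hits if h.strand == hairpin.SENSE]
        assert any(h.start == 100 and h.mismatches == 0 for h in sense)

    def test_one_mismatch_found_two_rejected(self):
        one = "C" + self.mature[1:] if self.mature[0] != "C" else "G" + self.mature[1:]
        two = one[:-1] + ("C" if one[-1] != "C" else "G")
        hits1 = hairpin.scan_mature({"t": self._host(one)}, {"m": self.mature})
        hits2 = hairpin.scan_mature({"t": self._host(two)}, {"m": self.mature})
        assert any(h.mismatches == 1 for h in hits1)
        assert not hits2

    def test_reverse_complement_is_antisense(self):
        seq = self._host(hairpin.revcomp(self.mature))
        hits = hairpin.scan_mature({"t": seq}, {"m": self.mature})
        assert any(h.strand == hairpin.ANTISENSE and h.start == 100 for h in hits)

    def test_u_t_equivalence(self):
        rna = self.mature.replace("T", "U")
        seq = self._host(self.mature)
        assert hairpin.scan_mature({"t": seq}, {"m": rna})

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            hairpin.scan_mature({"t": "ACGT" * 100}, {})

    def test_reference_length_validated(self):
        with pytest.raises(ValueError):
            hairpin.scan_mature({"t": "ACGT" * 100}, {"m": "ACGT"})


class TestExtractPrecursors:
    def _hit(self, start, tid="t"):
        return hairpin.MatureHit(tid, hairpin.SENSE, start, "A" * 22, "m", "m", 0)

    def test_default_ladder_window_lengths(self):
        seq = "C" * 600
        cands = hairpin.extract_precursors(self._hit(280), seq)
        lengths = sorted(len(c.sequence) for c in cands)
        assert lengths[0] == 42 and lengths[-1] == 242
        assert lengths == [22 + 2 * f for f in hairpin.DEFAULT_FLANKS]

    def test_start_boundary_clipping(self):
        seq = "C" * 400
        cands = hairpin.extract_precursors(self._hit(0), seq)
        assert cands  # clipped, not rejected
        assert all(c.window_start == 0 for c in cands)
        assert all(c.mature_offset == 0 for c in cands)

    def test_windows_contain_mature_at_offset(self):
        rng = np.random.default_rng(1)
        seq = _rand_seq(rng, 500)
        mature = seq[240:262]
        for strand in (hairpin.SENSE, hairpin.ANTISENSE):
            planted = mature if strand == hairpin.SENSE else hairpin.revcomp(mature)
            hit = hairpin.MatureHit("t", strand, 240, planted, "m", "m", 0)
            for cand in hairpin.extract_precursors(hit, seq):
                lo, hi = cand.mature_span
                assert cand.sequence[lo:hi] == planted

    def test_hit_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            hairpin.extract_precursors(self._hit(390), "C" * 400)


class TestFold:
    def test_poly_a_unpaired(self):
        structure, mfe = hairpin.fold("A" * 30)
        assert structure == "." * 30
        assert mfe == 0.0

    def test_perfect_inverted_repeat(self):
        rng = np.random.default_rng(2)
        stem = _rand_seq(rng, 20)
        seq = stem + "AACAAA" + hairpin.revcomp(stem)
        structure, mfe = hairpin.fold(seq)
        assert structure.count("(") == 20
        assert structure[:20] == "(" * 20
        assert structure[-20:] == ")" * 20
        assert mfe < 0

    def test_balanced_brackets_on_random_input(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = _rand_seq(rng, int(rng.integers(10, 150)))
            structure, mfe = hairpin.fold(seq)
            assert len(structure) == len(seq)
            hairpin.pair_table(structure)  # raises on imbalance
            assert mfe <= 0

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        seq = _rand_seq(rng, 120)
        assert hairpin.fold(seq) == hairpin.fold(seq)

    def test_vienna_engine_contract(self):
        # thermodynamic engine: same interface, valid structure, mfe <= 0
        pytest.importorskip("RNA")
        structure, mfe = hairpin.fold("GGGGAAAACCCC", engine="vienna")
        assert len(structure) == 12
        hairpin.pair_table(structure)
        assert mfe <= 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hairpin.fold("")

    def test_unknown_engine(self):
        with pytest.raises(ValueError):
            hairpin.fold("ACGU", engine="mystery")


class TestPairTable:
    def test_roundtrip(self):
        pt = hairpin.pair_table("((..))")
        assert pt == [5, 4, -1, -1, 1, 0]

    @pytest.mark.parametrize("bad", ["((.", "))((", "(.x)"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            hairpin.pair_table(bad)


class TestMfei:
    def test_arithmetic(self):
        amfe, idx = hairpin.mfei(-40.0, 100, 40.0)
        assert amfe == -40.0
        assert idx == -1.0

    def test_zero_mfe(self):
        assert hairpin.mfei(0.0, 100, 50.0) == (0.0, 0.0)

    def test_length_proportionality(self):
        amfe1, _ = hairpin.mfei(-30.0, 100, 50.0)
        amfe2, _ = hairpin.mfei(-30.0, 200, 50.0)
        assert amfe2 == amfe1 / 2

    def test_invalid_gc(self):
        with pytest.raises(ValueError):
            hairpin.mfei(-10.0, 100, 0.0)


class TestInferStar:
    def test_perfect_stem_mirror_with_overhang(self):
        rng = np.random.default_rng(5)
        mature = _rand_seq(rng, 22)
        seq = mature + "AAAAAA" + hairpin.revcomp(mature) + "CC"
        structure, _ = hairpin.fold(seq)
        pt = hairpin.pair_table(structure)
        star = hairpin.infer_star(pt, (0, 22), len(seq))
        assert star.core == (28, 50)
        assert star.reported == (28, 52)  # 2-nt 3' overhang

    def test_unpaired_mature_has_no_star(self):
        structure = "." * 40
        assert hairpin.infer_star(hairpin.pair_table(structure), (5, 27), 40) is None

    def test_star_length_close_to_mature_on_planted_set(self, small_bundle):
        matures = small_bundle.reference_matures
        for locus in small_bundle.truth.hairpins:
            if locus.violation != "none":
                continue
            mature = matures[locus.mature_name]
            hit = hairpin.MatureHit(
                locus.transcript_id, locus.strand, locus.mature_start,
                mature, locus.mature_name, locus.mature_name, 0,
            )
            ok, _, ev = hairpin.evaluate_hit(
                hit, small_bundle.transcripts[locus.transcript_id]
            )
            assert ok
            slo, shi = ev.star.core
            assert len(mature) - 4 <= shi - slo <= len(mature) + 4


def _loop_oracle(structure: str, envelope: tuple[int, int]):
    """Independent loop decomposition: nesting-tree hairpin loops.

    Builds the bracket tree recursively and reports leaf (hairpin) loops
    whose closing pair lies inside the envelope.
    """
    pt = hairpin.pair_table(structure)

    def children(i, j):
        out, k = [], i + 1
        while k < j:
            if pt[k] > k:
                out.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        return out

    loops = []

    def walk(i, j):
        kids = children(i, j)
        if not kids:
            loops.append((i, j))
        for a, b in kids:
            walk(a, b)

    for a, b in children(-1, len(pt)):
        walk(a, b)
    lo, hi = envelope
    return [(i, j) for i, j in loops if i >= lo and j < hi]


class TestEvaluateHairpin:
    def test_planted_valid_all_pass(self, small_bundle):
        table = small_bundle  # alias for readability
        valid = {h.mature_name for h in table.truth.hairpins if h.violation == "none"}
        res = hairpin.discover(table.transcripts, table.reference_matures)
        assert res.accepted_matures == valid

    def test_five_unpaired_in_mature_fails_only_c1(self):
        rng = np.random.default_rng(6)
        host = _rand_seq(rng, 500)
        mature = _rand_seq(rng, 22)
        seq, locus = simulate.plant_hairpin(host, mature, "mismatch_budget", seed=3)
        hit = hairpin.MatureHit("t", locus.strand, locus.mature_start, mature, "m", "m", 0)
        ok, _, ev = hairpin.evaluate_hit(hit, seq)
        assert not ok
        assert ev.failed_criteria == ["c1"]
        assert ev.mature_mismatches >= 5

    def test_branch_between_arms_fails_only_c3(self):
        rng = np.random.default_rng(7)
        host = _rand_seq(rng, 500)
        mature = _rand_seq(rng, 22)
        seq, locus = simulate.plant_hairpin(host, mature, "multiloop", seed=4)
        hit = hairpin.MatureHit("t", locus.strand, locus.mature_start, mature, "m", "m", 0)
        ok, _, ev = hairpin.evaluate_hit(hit, seq)
        assert not ok and ev.failed_criteria == ["c3"]

    def test_verdict_implies_every_criterion(self, small_bundle):
        res = hairpin.discover(small_bundle.transcripts, small_bundle.reference_matures)
        accepted = res.table[res.table["accepted"]]
        assert not accepted.empty
        assert accepted[["c1", "c2", "c3", "c4"]].all().all()

    def test_loop_decomposition_oracle_small_precursors(self):
        # on short windows the c3/c4 calls must match a brute-force
        # decomposition of the dot-bracket string
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(40):
            mature = _rand_seq(rng, 21)
            spacer = _rand_seq(rng, 4)
            loop = "A" * int(rng.integers(4, 8))
            seq = mature + spacer + loop + hairpin.revcomp(spacer) + hairpin.revcomp(mature)
            if len(seq) > 60:
                continue
            cand = hairpin.HairpinCandidate("t", hairpin.SENSE, 0, len(seq), seq, 0, 21)
            cand = hairpin.fold_candidate(cand)
            ev = hairpin.evaluate_hairpin(cand)
            if ev.star is None:
                continue
            slo, shi = ev.star.core
            env = (min(0, slo), max(21, shi))
            loops = _loop_oracle(cand.structure, env)
            assert ev.c3_no_multiloop == (len(loops) == 1)
            overlap = any(
                not (j < 0 or i >= 21) or not (j < slo or i >= shi)
                for i, j in loops
            )
            assert ev.c4_not_in_loop == (not overlap)
            checked += 1
        assert checked >= 20

    def test_unfolded_candidate_rejected(self):
        cand = hairpin.HairpinCandidate("t", hairpin.SENSE, 0, 40, "A" * 40, 5, 22)
        with pytest.raises(ValueError):
            hairpin.evaluate_hairpin(cand)


class TestDiscover:
    def test_strand_symmetry(self, small_bundle):
        fwd = hairpin.discover(small_bundle.transcripts, small_bundle.reference_matures)
        flipped = {t: hairpin.revcomp(s) for t, s in small_bundle.transcripts.items()}
        rev = hairpin.discover(flipped, small_bundle.reference_matures)
        assert fwd.accepted_matures == rev.accepted_matures
        key = ["mature", "transcript_id"]
        f = fwd.table.sort_values(key + ["strand"]).reset_index(drop=True)
        r = rev.table.sort_values(key + ["strand"], ascending=[True, True, False]).reset_index(drop=True)
        swap = {hairpin.SENSE: hairpin.ANTISENSE, hairpin.ANTISENSE: hairpin.SENSE}
        assert list(f["strand"].map(swap)) == list(r["strand"])
        assert list(f["accepted"]) == list(r["accepted"])

    def test_mature_on_two_transcripts(self):
        rng = np.random.default_rng(9)
        mature = _rand_seq(rng, 22)
        transcripts = {}
        for tid in ("c1_g1_i1", "c2_g1_i1"):
            host = _rand_seq(rng, 500)
            seq, _ = simulate.plant_hairpin(
                host, mature, "none", seed=int(rng.integers(2**31))
            )
            transcripts[tid] = seq
        res = hairpin.discover(transcripts, {"syn-miR-x": mature})
        assert res.accepted_matures == {"syn-miR-x"}
        accepted = res.table[res.table["accepted"]]
        assert set(accepted["transcript_id"]) == set(transcripts)

    def test_attribution_follows_precursor_activity(self, small_bundle):
        res = hairpin.discover(
            small_bundle.transcripts,
            small_bundle.reference_matures,
            fpkm=small_bundle.fpkm,
            groups=small_bundle.config.groups,
        )
        from lncmir import expression

        _, patterns = expression.sample_specific_sets(
            small_bundle.fpkm, small_bundle.config.groups
        )
        accepted = res.table[res.table["accepted"]]
        for mature in res.accepted_matures:
            tids = set(accepted[accepted["mature"] == mature]["transcript_id"])
            expect = frozenset().union(
                *(patterns.get(t, frozenset()) for t in tids)
            )
            assert res.attribution[mature] == expect

    def test_recovered_length_ranges(self, small_bundle):
        res = hairpin.discover(small_bundle.transcripts, small_bundle.reference_matures)
        accepted = res.table[res.table["accepted"]]
        matures = small_bundle.reference_matures
        for row in accepted.itertuples(index=False):
            assert 21 <= len(matures[row.mature]) <= 23
            assert 42 <= row.precursor_len <= 242
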