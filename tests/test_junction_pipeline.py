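"""Junction scanning, circular alignment, pileup and editing-site calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import circtau as ct
from circtau.junction_pipeline import match_pair, pileup_to_frame
from circtau.synthetic_data import SimulationConfig, simulate_reads


@pytest.fixture(scope="module")
def circle288():
    return ct.random_circle(288, np.random.default_rng(2024), name="ref288")


def make_pileup(length, pos, a=0, c=0, g=0, t=0):
    pile = ct.Pileup(length)
    pile.counts[pos - 1] = [a, c, g, t]
    return pile


class TestScanFastq:
    def write_pair(self, tmp_path, pairs):
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        with open(r1, "w") as f1, open(r2, "w") as f2:
            for rid, s1, s2 in pairs:
                f1.write(f"@{rid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{'I' * len(s2)}\n")
        return r1, r2

    def test_anchor_bearing_pair_recruited(self, tmp_path, circle288):
        anchor = ct.junction_anchor(circle288, 30)
        junction_read = circle288.subseq(circle288.length - 40, 80)  # crosses junction
        inside_read = circle288.subseq(10, 80)  # no junction crossing
        r1, r2 = self.write_pair(
            tmp_path,
            [
                ("pos", junction_read, ct.reverse_complement(junction_read)),
                ("neg", inside_read, ct.reverse_complement(inside_read)),
            ],
        )
        out1, out2 = tmp_path / "hit_R1.fastq", tmp_path / "hit_R2.fastq"
        result = ct.scan_fastq(r1, r2, anchor, out_r1=out1, out_r2=out2)
        assert result.n_pairs == 2
        assert result.pair_ids == ["pos/1"]
        assert {(h.mate, h.offset) for h in result.hits} == {("R1", 26), ("R2", 24)}
        assert out1.read_text().count("@") == 1  # both mates of the pair written
        assert out2.read_text().count("@") == 1

    def test_case_insensitive_match(self, circle288):
        anchor = ct.junction_anchor(circle288, 30)
        read = circle288.subseq(circle288.length - 14, 40).lower()
        o1, o2 = match_pair(read, "T" * 40, anchor)
        assert o1 == 0 and o2 == -1

    def test_unstranded_finds_swapped_orientation(self, circle288):
        anchor = ct.junction_anchor(circle288, 30)
        sense = circle288.subseq(circle288.length - 14, 40)
        o1, o2 = match_pair(ct.reverse_complement(sense), sense, anchor)
        assert o1 == -1 and o2 == -1
        o1, o2 = match_pair(ct.reverse_complement(sense), sense, anchor, unstranded=True)
        assert o1 >= 0 and o2 >= 0

    def test_record_count_mismatch_rejected(self, tmp_path):
        r1, r2 = self.write_pair(tmp_path, [("a", "ACGT", "ACGT"), ("b", "ACGT", "ACGT")])
        with open(r2, "w") as fh:
            fh.write("@a/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="mismatch at pair index 2"):
            ct.scan_fastq(r1, r2, ct.JunctionAnchor("ACGT"))

    def test_simulated_junction_reads_all_recovered(self, circle288):
        """Every pair whose mate fully contains the anchor is recruited,
        verified against brute-force coordinate bookkeeping from the
        simulator's ground truth (error-free reads)."""
        cfg = SimulationConfig(
            circ=circle288,
            editing_truth={"s": {}},
            coverage=100,
            error_rate=0.0,
            seed=7,
        )
        reads, truth = simulate_reads(cfg)
        anchor = ct.junction_anchor(circle288, 30)
        L, rl = circle288.length, cfg.read_length
        anchor_start0 = L - 15  # 0-based start of the 30-mer anchor on the circle
        for pair in reads["s"]:
            start0 = pair.start - 1
            ins = pair.insert
            off_r1 = (anchor_start0 - start0) % L
            in_r1 = off_r1 + 30 <= rl
            frag_end0 = start0 + ins  # exclusive, unwrapped
            off_in_frag = off_r1 if off_r1 + 30 <= ins else None
            in_r2 = off_in_frag is not None and off_in_frag >= ins - rl
            o1, o2 = match_pair(pair.r1, pair.r2, anchor)
            assert (o1 >= 0) == in_r1
            assert (o2 >= 0) == in_r2


class TestAlignCircular:
    def test_exact_junction_crossing_read_wraps(self, circle288):
        read = circle288.subseq(circle288.length - 24, 50)
        pl = ct.align_circular(read, circle288)
        assert pl is not None
        assert pl.start == circle288.length - 24
        assert pl.identity == 1.0
        covered = {pos for pos, _ in pl.pairs}
        assert 1 in covered and circle288.length in covered

    def test_planted_edit_recorded_as_G_over_A(self, circle288):
        a_pos = circle288.sequence.index("A", 40) + 1
        read = list(circle288.subseq(a_pos - 20, 50))
        read[20] = "G"
        pl = ct.align_circular("".join(read), circle288)
        assert pl is not None
        assert (a_pos, "G") in pl.pairs
        assert pl.identity >= 0.9

    def test_reverse_complement_read_counted_on_sense(self, circle288):
        read = ct.reverse_complement(circle288.subseq(30, 50))
        pl = ct.align_circular(read, circle288)
        assert pl is not None
        assert pl.strand == "-"
        assert all(circle288.base(pos) == base for pos, base in pl.pairs)

    def test_unrelated_read_rejected(self, circle288):
        assert ct.align_circular("T" * 50, circle288) is None

    def test_empty_read_rejected(self, circle288):
        with pytest.raises(ValueError, match="empty read"):
            ct.align_circular("", circle288)


class TestPileup:
    def test_identical_reads_depth(self, circle288):
        read = circle288.subseq(1, 50)
        placements = [ct.align_circular(read, circle288) for _ in range(10)]
        pile = ct.build_pileup(placements, circle288)
        assert all(pile.depth(p) == 10 for p in range(1, 51))
        assert all(pile.depth(p) == 0 for p in range(51, 289))

    def test_base_composition(self):
        pile = make_pileup(10, 4, a=990, g=10)
        assert pile.base_count(4, "A") == 990
        assert pile.base_count(4, "G") == 10
        assert pile.depth(4) == 1000

    def test_matches_simulator_truth_counts(self, circle288):
        cfg = SimulationConfig(
            circ=circle288,
            editing_truth={"s": {}},
            coverage=30,
            error_rate=0.0,
            seed=3,
        )
        reads, truth = simulate_reads(cfg)
        placements = []
        for p in reads["s"]:
            placements.append(ct.align_circular(p.r1, circle288, read_id=p.read_id))
            placements.append(ct.align_circular(p.r2, circle288, read_id=p.read_id))
        pile = ct.build_pileup(placements, circle288)
        L, rl = circle288.length, cfg.read_length
        expected = np.zeros(L, dtype=int)
        for p in reads["s"]:
            s0 = p.start - 1
            for off in list(range(rl)) + list(range(p.insert - rl, p.insert)):
                expected[(s0 + off) % L] += 1
        assert np.array_equal(pile.depths, expected)

    def test_pileup_frame_schema(self, circle288):
        pile = ct.Pileup(circle288.length)
        frame = pileup_to_frame({"s": pile}, circle288)
        assert list(frame.columns) == ["position", "ref", "A", "C", "G", "T", "depth", "sample"]
        assert len(frame) == circle288.length


class TestCallSites:
    def test_exact_one_percent_boundary_called(self):
        pile = make_pileup(10, 4, a=990, g=10)
        sites = ct.call_sites({"s": pile}, "C" * 3 + "A" + "C" * 6)
        assert [(s.position, s.called) for s in sites] == [(4, True)]
        assert sites[0].g_fraction == pytest.approx(0.01)

    def test_below_threshold_not_called(self):
        pile = make_pileup(10, 4, a=991, g=9)
        assert ct.call_sites({"s": pile}, "C" * 3 + "A" + "C" * 6) == []

    def test_non_A_reference_never_called(self):
        pile = make_pileup(10, 4, c=500, g=500)
        assert ct.call_sites({"s": pile}, "C" * 10) == []

    def test_depth_floor(self):
        pile = make_pileup(10, 4, a=8, g=1)
        ref = "C" * 3 + "A" + "C" * 6
        assert ct.call_sites({"s": pile}, ref) == []
        relaxed = ct.CallerConfig(min_depth=0)
        assert [s.position for s in ct.call_sites({"s": pile}, ref, relaxed)] == [4]

    def test_called_in_one_sample_reports_all_samples(self):
        ref = "C" * 3 + "A" + "C" * 6
        piles = {
            "ADAR2": make_pileup(10, 4, a=900, g=100),
            "GFP": make_pileup(10, 4, a=998, g=2),
        }
        sites = ct.call_sites(piles, ref)
        by_sample = {s.sample: s for s in sites}
        assert by_sample["ADAR2"].called and not by_sample["GFP"].called
        assert by_sample["GFP"].g_fraction == pytest.approx(0.002)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ct.call_sites({"s": ct.Pileup(5)}, "A" * 6)

    @given(
        a=st.integers(0, 200),
        g=st.integers(0, 50),
        frac1=st.floats(0.005, 0.05),
        dfrac=st.floats(0.0, 0.05),
        depth1=st.integers(0, 30),
        ddepth=st.integers(0, 30),
    )
    def test_threshold_monotonicity(self, a, g, frac1, dfrac, depth1, ddepth):
        pile = make_pileup(3, 2, a=a, g=g)
        ref = "CAC"
        loose = ct.CallerConfig(min_g_fraction=frac1, min_depth=depth1)
        strict = ct.CallerConfig(min_g_fraction=frac1 + dfrac, min_depth=depth1 + ddepth)
        called_loose = {s.position for s in ct.call_sites({"s": pile}, ref, loose) if s.called}
        called_strict = {s.position for s in ct.call_sites({"s": pile}, ref, strict) if s.called}
        assert called_strict <= called_loose

    def test_no_false_positives_under_binomial_error_model(self):
        """At 10,000x and 0.1% error, A>G noise cannot reach the 1% rule."""
        rng = np.random.default_rng(5)
        ref = ct.random_circle(288, rng).sequence
        pile = ct.Pileup(288)
        depth = 10_000
        for pos in range(1, 289):
            g = rng.binomial(depth, 0.001 / 3)
            other = rng.binomial(depth, 0.001 / 3, size=2).sum()
            pile.counts[pos - 1] = [depth - g - other, other, g, 0]
            if ref[pos - 1] != "A":
                pile.counts[pos - 1] = [0, depth, 0, 0]
        assert ct.call_sites({"s": pile}, ref) == []

    def test_origin_invariance_of_calling(self, circle288):
        """Calling on a rotated reference yields the same site set after
        position remapping."""
        edited = {50: 1.0, 200: 1.0}
        # make truth positions adenosines by construction: plant A's first
        seq = list(circle288.sequence)
        seq[49], seq[199] = "A", "A"
        circ = ct.CircRNA.from_sequence("ref", "".join(seq))
        cfg = SimulationConfig(
            circ=circ, editing_truth={"s": edited}, coverage=60, error_rate=0.0, seed=11
        )
        reads, _ = simulate_reads(cfg)

        def call_on(reference):
            placements = []
            for p in reads["s"]:
                placements.append(ct.align_circular(p.r1, reference))
                placements.append(ct.align_circular(p.r2, reference))
            pile = ct.build_pileup(placements, reference)
            return {s.position for s in ct.call_sites({"s": pile}, reference) if s.called}

        origin = 123
        rotated = ct.rotate(circ, origin)
        base_sites = call_on(circ)
        rot_sites = call_on(rotated)
        assert base_sites == {50, 200}
        assert {(p - origin) % circ.length + 1 for p in base_sites} == rot_sites


class TestSummaries:
    def test_compare_samples_union_and_top(self):
        sites = [
            ct.EditingSite(219, "ADAR2", 0.16),
            ct.EditingSite(99, "ADAR2", 0.03),
            ct.EditingSite(99, "ADAR1", 0.02),
        ]
        summary = ct.compare_samples(sites)
        assert summary["per_sample"] == {"ADAR2": 2, "ADAR1": 1}
        assert summary["union"] == 2
        assert summary["top_site"] == {"position": 219, "sample": "ADAR2", "g_fraction": 0.16}

    @pytest.mark.parametrize(
        "count,ref,expected", [(60, 600, 0.1), (600, 600, 1.0)]
    )
    def test_normalize_expression(self, count, ref, expected):
        assert ct.normalize_expression(count, ref) == pytest.approx(expected)

    def test_fold_change_arithmetic(self):
        condition = ct.normalize_expression(60, 100)
        control = ct.normalize_expression(10, 100)
        assert condition / control == pytest.approx(6.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            ct.normalize_expression(60, 0)
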