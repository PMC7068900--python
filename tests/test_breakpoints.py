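import numpy as np
import pandas as pd
import pytest

from linkinv import breakpoints as bpv
from linkinv.align import revcomp
from linkinv.breakpoints import (BreakpointPair, NullCalibration,
                                 ReadAssignment, SupercontigSegment,
                                 assembly_validation, build_pangenome,
                                 calibrate_null, classify_supercontig,
                                 generate_artificial_breakpoints,
                                 validate_inversion)


def random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()


class TestPanGenome:
    def test_toy_junction_sequences(self, monkeypatch):
        # segment [4, 12) of GATTACAGATTACAGG with 4-bp flanks
        monkeypatch.setattr(bpv, "MIN_SPAN_BP", 1)
        pg = build_pangenome("GATTACAGATTACAGG",
                             BreakpointPair("t", "1", 4, 12), flank=4)
        assert pg.contigs["bp1_inv"] == "GATTTAAT"
        assert pg.contigs["bp2_inv"] == "CTGTCAGG"
        assert pg.contigs["bp1_ref"] == "GATTACAG"
        assert pg.contigs["bp2_ref"] == "ATTACAGG"  # seq[8:16]

    def test_reverse_complement_round_trip(self):
        """Building the pan-genome on an already-inverted chromosome
        recovers the original reference junctions exactly."""
        ref = random_seq(60_000, seed=1)
        s, e = 20_000, 40_000
        inverted = ref[:s] + revcomp(ref[s:e]) + ref[e:]
        pg_ref = build_pangenome(ref, BreakpointPair("x", "1", s, e), 5_000)
        pg_inv = build_pangenome(inverted, BreakpointPair("x", "1", s, e), 5_000)
        assert pg_inv.contigs["bp1_inv"] == pg_ref.contigs["bp1_ref"]
        assert pg_inv.contigs["bp2_inv"] == pg_ref.contigs["bp2_ref"]

    def test_background_masks_breakpoint_neighbourhoods(self):
        ref = random_seq(80_000, seed=2)
        pg = build_pangenome(ref, BreakpointPair("x", "1", 30_000, 50_000),
                             5_000, include_background=True)
        assert pg.background[25_000:35_000] == "N" * 10_000
        assert pg.background[45_000:55_000] == "N" * 10_000
        assert pg.background[:25_000] == ref[:25_000]

    def test_flank_below_span_rule_is_config_error(self):
        with pytest.raises(ValueError):
            build_pangenome(random_seq(10_000), BreakpointPair("x", "1", 3000, 6000),
                            flank=500)


@pytest.fixture(scope="module")
def pangenome():
    return build_pangenome(random_seq(200_000, seed=3),
                           BreakpointPair("x", "1", 80_000, 140_000),
                           10_000)


class TestAssignReads:
    def test_junction_spanning_inverted_read(self, pangenome):
        # exact 6-kb substring of bp1_inv centred on the junction
        read = pangenome.contigs["bp1_inv"][7_000:13_000]
        [a] = bpv.assign_reads([("r1", read)], pangenome)
        assert (a.breakpoint, a.orientation) == ("bp1", "inv")
        assert (a.left_span, a.right_span) == (3_000, 3_000)

    def test_read_ending_at_junction_fails_dual_span(self, pangenome):
        read = pangenome.contigs["bp1_ref"][4_000:10_000]  # ends at junction
        [a] = bpv.assign_reads([("r1", read)], pangenome)
        assert a.orientation == "unassigned"
        assert a.right_span == 0

    def test_reads_at_or_below_length_cut_are_skipped(self, pangenome):
        read = pangenome.contigs["bp1_ref"][5_000:10_000]  # exactly 5 kb
        assert bpv.assign_reads([("r1", read)], pangenome) == []

    def test_equal_scores_on_ref_and_inv_are_ambiguous(self):
        # construct a reference whose bp1_inv equals bp1_ref: the right
        # flank of the segment is the reverse complement of its start
        left = random_seq(10_000, seed=4)
        x = random_seq(10_000, seed=5)
        mid = random_seq(30_000, seed=6)
        right = random_seq(10_000, seed=7)
        ref = left + x + mid + revcomp(x) + right
        s, e = 10_000, 60_000
        pg = build_pangenome(ref, BreakpointPair("p", "1", s, e), 10_000)
        assert pg.contigs["bp1_ref"] == pg.contigs["bp1_inv"]
        read = ref[s - 3_000:s + 3_000]
        [a] = bpv.assign_reads([("r1", read)], pg)
        assert a.orientation == "ambiguous"

    def test_off_target_read_lands_on_background_unassigned(self):
        ref = random_seq(200_000, seed=8)
        pg = build_pangenome(ref, BreakpointPair("x", "1", 80_000, 140_000),
                             10_000, include_background=True)
        read = ref[180_000:188_000]  # far from both junctions
        [a] = bpv.assign_reads([("r1", read)], pg)
        assert a.orientation == "unassigned"


@pytest.fixture(scope="module")
def setting():
    rng = np.random.default_rng(9)
    seqs = {"1": random_seq(400_000, 10)}
    rows = [("1", int(s), int(s) + 2_000, "fam0")
            for s in rng.integers(0, 398_000, size=40)]
    repeats = pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])
    return seqs, repeats


class TestArtificialBreakpoints:
    def test_deterministic_under_seed(self, setting):
        seqs, repeats = setting
        cands = [BreakpointPair("c", "1", 100_000, 150_000)]
        a = generate_artificial_breakpoints(seqs, repeats, cands, 20, seed=5,
                                            flank=5_000)
        b = generate_artificial_breakpoints(seqs, repeats, cands, 20, seed=5,
                                            flank=5_000)
        assert [(p.chrom, p.bp1, p.bp2) for p in a] == \
               [(p.chrom, p.bp1, p.bp2) for p in b]

    def test_n_zero_gives_empty_list(self, setting):
        seqs, repeats = setting
        assert generate_artificial_breakpoints(
            seqs, repeats, [BreakpointPair("c", "1", 100_000, 150_000)],
            0, seed=1) == []

    def test_repeat_matching_of_clean_candidates(self, setting):
        seqs, _ = setting
        no_repeats = pd.DataFrame(columns=["chrom", "start", "end", "family"])
        cands = [BreakpointPair("c", "1", 100_000, 150_000)]
        pairs = generate_artificial_breakpoints(seqs, no_repeats, cands,
                                                30, seed=2, flank=5_000)
        fracs = bpv.candidate_repeat_fractions(seqs, no_repeats, pairs, 5_000)
        assert np.all(fracs <= 0.10)  # within tolerance of 0%-repeat targets


class TestNullCalibration:
    def test_quartiles_match_hand_enumeration(self):
        # five-point set {10,12,14,16,18}: linear-interpolation quartiles
        assignments = []
        for cov in (10, 12, 14, 16, 18):
            a = [ReadAssignment(f"r{i}", "bp1", "ref", 2000, 2000)
                 for i in range(cov)]
            a += [ReadAssignment(f"q{i}", "bp2", "ref", 2000, 2000)
                  for i in range(cov)]
            assignments.append(a)
        null = calibrate_null(assignments)
        q1, q2, q3 = null.coverage_quartiles()
        assert (q1, q2, q3) == (12.0, 14.0, 16.0)
        assert null.coverage_iqr == 4.0

    def test_all_clean_null_has_zero_misassignment(self):
        a = [[ReadAssignment(f"r{i}", bp, "ref", 2000, 2000)
              for i in range(20) for bp in ("bp1", "bp2")]]
        assert calibrate_null(a).misassignment_rate() == 0.0

    def test_single_contaminated_breakpoint_rate(self):
        covs = np.full(1000, 30.0)
        fracs = np.zeros(1000)
        fracs[0] = 0.5
        null = NullCalibration(covs, fracs)
        assert null.misassignment_rate(0.37) == pytest.approx(0.001)

    def test_all_zero_coverage_is_calibration_failure(self):
        with pytest.raises(ValueError):
            NullCalibration(np.zeros(5), np.full(5, np.nan))


class TestValidateInversion:
    @pytest.fixture
    def null(self):
        rng = np.random.default_rng(1)
        return NullCalibration(rng.integers(15, 25, 200).astype(float),
                               np.zeros(200))

    def _assignments(self, n_inv1, n_ref1, n_inv2, n_ref2):
        out = []
        for bp, n_inv, n_ref in (("bp1", n_inv1, n_ref1),
                                 ("bp2", n_inv2, n_ref2)):
            out += [ReadAssignment(f"{bp}i{i}", bp, "inv", 2000, 2000)
                    for i in range(n_inv)]
            out += [ReadAssignment(f"{bp}r{i}", bp, "ref", 2000, 2000)
                    for i in range(n_ref)]
        return out

    def test_forty_percent_both_breakpoints_is_valid(self, null):
        res = validate_inversion(self._assignments(4, 6, 4, 6), null)
        assert res.overall_valid

    def test_nine_x_coverage_discards_breakpoint(self, null):
        res = validate_inversion(self._assignments(9, 0, 8, 8), null)
        assert not res.overall_valid
        assert "coverage 9" in res.breakpoints["bp1"].reason

    def test_fraction_exactly_37_percent_fails(self, null):
        res = validate_inversion(self._assignments(37, 63, 37, 63), null)
        assert not res.overall_valid
        assert res.breakpoints["bp1"].inverted_fraction == pytest.approx(0.37)

    def test_coverage_above_null_fence_discarded(self, null):
        _, hi = null.coverage_fences(2.0)
        n = int(hi) + 10
        res = validate_inversion(self._assignments(n, n, 10, 10), null)
        assert not res.breakpoints["bp1"].coverage_pass
        assert res.breakpoints["bp2"].passes

    def test_no_reads_reports_no_coverage(self, null):
        res = validate_inversion([], null)
        assert not res.overall_valid
        assert res.breakpoints["bp1"].reason == "no coverage"


class TestSupercontigs:
    call = BreakpointPair("x", "1", 1_000_000, 1_400_000)

    def test_inverted_bp1_signature(self):
        segs = [SupercontigSegment(960_000, 999_000, +1, 80),
                SupercontigSegment(1_360_000, 1_399_000, -1, 80)]
        res = classify_supercontig(segs, self.call, 80_000)
        assert res["bp1"] and res["supports_inversion"]

    def test_colinear_reference_configuration_no_support(self):
        segs = [SupercontigSegment(960_000, 999_000, +1, 80),
                SupercontigSegment(1_001_000, 1_040_000, +1, 80)]
        assert not classify_supercontig(segs, self.call, 80_000)[
            "supports_inversion"]

    def test_single_colinear_segment_no_support(self):
        segs = [SupercontigSegment(980_000, 1_020_000, +1, 70)]
        assert not classify_supercontig(segs, self.call, 50_000)[
            "supports_inversion"]

    def test_score_and_length_gates(self):
        segs = [SupercontigSegment(960_000, 999_000, +1, 60),
                SupercontigSegment(1_360_000, 1_399_000, -1, 60)]
        # score not strictly above 60 -> no usable segments
        assert not classify_supercontig(segs, self.call, 80_000)[
            "supports_inversion"]
        good = [SupercontigSegment(960_000, 999_000, +1, 90),
                SupercontigSegment(1_360_000, 1_399_000, -1, 90)]
        # supercontig itself too short
        assert not classify_supercontig(good, self.call, 9_000)[
            "supports_inversion"]

    def test_assembly_validation_needs_both_junctions(self):
        bp1 = [SupercontigSegment(960_000, 999_000, +1, 80),
               SupercontigSegment(1_360_000, 1_399_000, -1, 80)]
        bp2 = [SupercontigSegment(1_001_000, 1_040_000, -1, 80),
               SupercontigSegment(1_401_000, 1_440_000, +1, 80)]
        assert not assembly_validation([(bp1, 80_000)], self.call)
        assert assembly_validation([(bp1, 80_000), (bp2, 80_000)], self.call)


def test_heterozygous_carrier_fraction_near_half(default_sim):
    """Reads pooled from one carrier and one reference haplotype give an
    inverted fraction near 0.5 at both junctions."""
    from linkinv.simulate import junction_reads

    sim = default_sim
    inv = next(i for i in sim.truth.inversions if i.is_micro)
    carrier = inv.carriers[0]
    other = (carrier[0], 1 - carrier[1])
    sources = [carrier] + ([other] if other not in inv.carriers
                           else [(carrier[0], carrier[1])])
    rng = np.random.default_rng(21)
    reads = junction_reads(sim.reference, sim.truth, inv.pair, 40, rng,
                           sim.config.read_model, samples=sources)
    pg = build_pangenome(sim.reference.seqs[inv.chrom], inv.pair, 10_000)
    asn = bpv.assign_reads(reads, pg)
    for bp in ("bp1", "bp2"):
        n_inv, n_ref = bpv.breakpoint_counts(asn, bp)
        frac = n_inv / (n_inv + n_ref)
        expected = 0.5 if other not in inv.carriers else 1.0
        assert abs(frac - expected) < 0.25
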