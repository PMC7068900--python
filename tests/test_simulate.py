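import numpy as np
import pytest

from linkinv.align import revcomp
from linkinv.simulate import (AdmixtureEvent, CallerProfile, ColonySpec,
                              InversionSpec, ReadModel, SimConfig,
                              haplotype_sequence, realized_n50,
                              simulate_all, simulate_candidate_calls,
                              simulate_long_reads, simulate_reference,
                              simulate_panel)


def small_config(seed=0, **overrides):
    base = dict(
        seed=seed, chrom_lengths={"1": 600_000, "2": 600_000},
        repeat_density=0.2,
        colonies=[ColonySpec("U", "Aaa", 2, 3), ColonySpec("V", "Aaf", 2, 3),
                  ColonySpec("M", "sister", 1, 3)],
        admixture=[AdmixtureEvent("V", "U", 0.2, 100_000)],
        inversions=[InversionSpec("inv_a", 30_000, {"U": 1.0})])
    base.update(overrides)
    return SimConfig(**base)


class TestDeterminism:
    def test_every_output_reproducible_under_seed(self):
        a = simulate_all(small_config(seed=5))
        b = simulate_all(small_config(seed=5))
        assert a.reference.seqs == b.reference.seqs
        assert a.reference.repeats.equals(b.reference.repeats)
        assert np.array_equal(a.panel.genotypes, b.panel.genotypes)
        assert a.panel.sites.equals(b.panel.sites)
        assert a.truth.tracts.equals(b.truth.tracts)
        assert [(i.id, i.chrom, i.start, i.end, i.carriers)
                for i in a.truth.inversions] == \
               [(i.id, i.chrom, i.start, i.end, i.carriers)
                for i in b.truth.inversions]
        for caller in a.candidates:
            assert [(c.interval, c.sample) for c in a.candidates[caller]] == \
                   [(c.interval, c.sample) for c in b.candidates[caller]]

    def test_different_seeds_differ(self):
        a = simulate_all(small_config(seed=1))
        b = simulate_all(small_config(seed=2))
        assert a.reference.seqs != b.reference.seqs


class TestReference:
    def test_zero_density_gives_empty_annotation(self):
        ref = simulate_reference(small_config(repeat_density=0.0))
        assert len(ref.repeats) == 0

    def test_planted_density_near_target(self):
        ref = simulate_reference(small_config(repeat_density=0.3))
        for chrom, seq in ref.seqs.items():
            mask = np.zeros(len(seq), dtype=bool)
            for r in ref.repeats[ref.repeats["chrom"] == chrom].itertuples():
                mask[r.start:r.end] = True
            assert 0.25 <= mask.mean() <= 0.40

    def test_sequences_are_acgt(self):
        ref = simulate_reference(small_config())
        assert set(ref.seqs["1"][:10_000]) <= set("ACGT")


class TestPanel:
    def test_no_admixture_means_no_truth_tracts(self):
        cfg = small_config(admixture=[])
        ref = simulate_reference(cfg)
        _, _, truth = simulate_panel(cfg, ref)
        assert len(truth.tracts) == 0

    def test_stronger_drift_reduces_diversity(self):
        """A subspecies with larger Balding-Nichols drift shows lower pi."""
        from linkinv.popgen import window_diversity

        pis = {}
        for sub, f_a, f_b in (("low", 0.05, 0.4), ("high", 0.4, 0.05)):
            cfg = small_config(
                seed=31, admixture=[], inversions=[],
                f_split={"Aaa": f_a, "Aaf": f_b, "sister": 0.45})
            sim = simulate_all(cfg)
            df = window_diversity(sim.panel, "U", cfg.chrom_lengths, 600_000)
            pis[sub] = df["value"].mean()
        assert pis["high"] < pis["low"]

    def test_shared_admixture_tracts_common_to_all_founders(self):
        cfg = small_config(
            seed=8,
            admixture=[AdmixtureEvent("V", "U", 0.2, 150_000, shared=True)])
        sim = simulate_all(cfg)
        tracts = sim.truth.tracts
        u_samples = [s for s in sim.panel.samples if s.startswith("U")]
        per_hap = {(s, k): set(map(tuple, tracts[
            (tracts["sample"] == s) & (tracts["hap"] == k)]
            [["chrom", "start", "end"]].values))
            for s in u_samples for k in (0, 1)}
        reference_set = next(iter(per_hap.values()))
        assert all(v == reference_set for v in per_hap.values())


class TestInversions:
    def test_frequency_one_makes_every_haplotype_a_carrier(self):
        sim = simulate_all(small_config(seed=3))
        inv = sim.truth.inversions[0]
        u_samples = [s for s in sim.panel.samples if s.startswith("U")]
        assert set(inv.carriers) == {(s, k) for s in u_samples for k in (0, 1)}

    def test_frequency_zero_has_no_carriers_beyond_guarantee(self):
        cfg = small_config(
            seed=4, inversions=[InversionSpec("z", 30_000, {"U": 0.0})])
        with pytest.raises(Exception):
            simulate_all(cfg)  # no colony with positive frequency

    def test_carrier_sequence_is_cut_revcomp_paste(self):
        sim = simulate_all(small_config(seed=6))
        inv = sim.truth.inversions[0]
        sample, hap = inv.carriers[0]
        got = haplotype_sequence(sim.reference, sim.truth, sample, hap,
                                 inv.chrom)
        ref = sim.reference.seqs[inv.chrom]
        expected = (ref[:inv.start] + revcomp(ref[inv.start:inv.end])
                    + ref[inv.end:])
        assert got == expected

    def test_non_carrier_sequence_equals_reference(self):
        sim = simulate_all(small_config(seed=6))
        inv = sim.truth.inversions[0]
        non_carrier = next(s for s in sim.panel.samples
                           if (s, 0) not in inv.carriers)
        got = haplotype_sequence(sim.reference, sim.truth, non_carrier, 0,
                                 inv.chrom)
        assert got == sim.reference.seqs[inv.chrom]


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(1)
        seq = simulate_reference(small_config(repeat_density=0)).seqs["1"]
        model = ReadModel(error_rate=0.0)
        for _, read in simulate_long_reads(seq, 2.0, rng, model,
                                           window=(0, 100_000)):
            assert read in seq or revcomp(read) in seq

    def test_realized_n50_close_to_target(self):
        rng = np.random.default_rng(2)
        seq = "A" * 2_000_000
        model = ReadModel(n50=6789)
        reads = simulate_long_reads(seq, 3.0, rng, model)
        assert len(reads) >= 500
        n50 = realized_n50([len(r) for _, r in reads])
        assert abs(n50 - 6789) / 6789 < 0.15

    def test_fixed_seed_reproduces_reads(self):
        seq = simulate_reference(small_config()).seqs["1"]
        reads1 = simulate_long_reads(seq, 1.0, np.random.default_rng(7),
                                     window=(0, 50_000))
        reads2 = simulate_long_reads(seq, 1.0, np.random.default_rng(7),
                                     window=(0, 50_000))
        assert reads1 == reads2

    def test_zero_coverage_gives_no_reads(self):
        rng = np.random.default_rng(3)
        assert simulate_long_reads("ACGT" * 10_000, 0.0, rng) == []


class TestCandidateCalls:
    def test_perfect_caller_reproduces_truth(self):
        cfg = small_config(
            seed=9,
            callers=[CallerProfile("P", sens_micro=1.0, sens_large=1.0,
                                   jitter_sd=0.0, n_false_positives=0)])
        sim = simulate_all(cfg)
        truth_pairs = {(i.chrom, i.start, i.end, s)
                       for i in sim.truth.inversions
                       for s in {smp for smp, _ in i.carriers}}
        got = {(c.interval.chrom, c.interval.start, c.interval.end, c.sample)
               for c in sim.candidates["P"]}
        assert got == truth_pairs

    def test_blind_caller_emits_nothing(self):
        cfg = small_config(
            seed=9,
            callers=[CallerProfile("B", sens_micro=0.0, sens_large=0.0,
                                   n_false_positives=0)])
        sim = simulate_all(cfg)
        assert sim.candidates["B"] == []

    def test_false_positives_sit_at_repeat_loci(self):
        cfg = small_config(
            seed=10,
            inversions=[],
            callers=[CallerProfile("F", n_false_positives=15,
                                   fp_log10_size=(3.5, 4.0))])
        sim = simulate_all(cfg)
        ref = sim.reference
        masks = {}
        for chrom, seq in ref.seqs.items():
            m = np.zeros(len(seq), dtype=bool)
            for r in ref.repeats[ref.repeats["chrom"] == chrom].itertuples():
                m[r.start:r.end] = True
            masks[chrom] = m
        hits = [masks[c.interval.chrom][
                    (c.interval.start + c.interval.end) // 2]
                for c in sim.candidates["F"]]
        assert np.mean(hits) > 0.8

    def test_small_jitter_keeps_reciprocal_overlap_with_truth(self):
        from linkinv.intervals import reciprocal_overlap

        cfg = small_config(
            seed=11,
            callers=[CallerProfile("J", sens_micro=1.0, sens_large=1.0,
                                   jitter_sd=50.0, n_false_positives=0)])
        sim = simulate_all(cfg)
        for c in sim.candidates["J"]:
            inv = next(i for i in sim.truth.inversions
                       if i.chrom == c.interval.chrom)
            assert reciprocal_overlap(c.interval, inv.interval) >= 0.95


class TestSequenceOutput:
    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO
        from linkinv.simulate import write_reference_fasta

        ref = simulate_reference(small_config(seed=13))
        path = tmp_path / "ref.fa"
        write_reference_fasta(ref, str(path))
        back = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert back == ref.seqs

    def test_fastq_round_trip(self, tmp_path):
        from Bio import SeqIO
        from linkinv.simulate import write_reads_fastq

        rng = np.random.default_rng(4)
        seq = simulate_reference(small_config(seed=13)).seqs["1"]
        reads = simulate_long_reads(seq, 0.5, rng, window=(0, 60_000))
        path = tmp_path / "reads.fastq"
        write_reads_fastq(reads, str(path))
        back = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]
        assert back == reads
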