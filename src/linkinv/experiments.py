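"""Canned calibration and parameter-recovery experiments.

These functions wire the generator to the analysis stages under the study's
default conditions and report the quantities a method-validation run cares
about: the false-validation rate of the breakpoint classifier on a
repeat-matched uninverted null, recall of spiked inversions, genome-wide D
and tract-level fD across admixture fractions, fD peak recall, and bootstrap
support for the subspecies split. They are deterministic functions of their
seeds and are used by both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import breakpoints as bpv
from . import introgression as intro
from . import phylogeny as phylo
from .intervals import GenomicInterval
from .simulate import (AdmixtureEvent, ColonySpec, SimConfig, junction_reads,
                       simulate_all)
from .sv_merge import merge_candidates


def _null_calibration(sim, pairs, n_pairs: int, seed: int, coverage: float,
                      flank: int) -> bpv.NullCalibration:
    rng = np.random.default_rng([seed, 11])
    null_pairs = bpv.generate_artificial_breakpoints(
        sim.reference.seqs, sim.reference.repeats, pairs,
        n=n_pairs, seed=seed, flank=flank)
    assignments = []
    for pair in null_pairs:
        reads = junction_reads(sim.reference, sim.truth, pair, coverage, rng,
                               sim.config.read_model, samples=None, flank=flank)
        pg = bpv.build_pangenome(sim.reference.seqs[pair.chrom], pair, flank)
        assignments.append(bpv.assign_reads(reads, pg))
    return bpv.calibrate_null(assignments)


def null_false_validation(seed: int, n_pairs: int = 500,
                          coverage: float = 30.0, flank: int = 10_000
                          ) -> dict:
    """False-validation rate (%) of the breakpoint classifier on the null.

    Simulates the default toy study (three 5-Mb chromosomes, 30% repeats,
    caller-like candidates including repeat false positives), samples
    ``n_pairs`` artificial uninverted breakpoint pairs repeat-matched to the
    merged candidates (two junction breakpoints each), simulates ~``coverage``
    selected long reads per junction, and applies the full decision rule
    (1-kb dual span, >= 10x coverage, Q3 + 2 x IQR fence, > 37% inverted).
    """
    cfg = SimConfig(seed=seed)
    sim = simulate_all(cfg)
    candidates = [c for cl in sim.candidates.values() for c in cl]
    calls = merge_candidates(candidates)
    pairs = [bpv.BreakpointPair(c.id, c.interval.chrom, *c.breakpoints())
             for c in calls]
    null = _null_calibration(sim, pairs, n_pairs, seed, coverage, flank)
    rate = null.false_validation_rate()
    return {"rate_percent": 100.0 * rate,
            "n_breakpoints": null.n_regions,
            "null": null, "sim": sim, "pairs": pairs}


def inversion_validation_recall(seed: int,
                                null: bpv.NullCalibration | None = None,
                                n_null_pairs: int = 60,
                                coverage: float = 30.0,
                                flank: int = 10_000) -> dict:
    """Recall of spiked (clean-flank) inversions through the full validator.

    Mirroring the study's procedure — an inversion counts as validated when
    both junctions are reconstructed in *some* sample — each spiked
    inversion is attempted from reads of up to three distinct carrier
    samples (both haplotypes each, so heterozygous carriers contribute a
    ~50/50 read mixture) and is recalled if any attempt passes the default
    thresholds.
    """
    cfg = SimConfig(seed=seed)
    sim = simulate_all(cfg)
    pairs = [t.pair for t in sim.truth.inversions]
    if null is None:
        null = _null_calibration(sim, pairs, n_null_pairs, seed, coverage, flank)
    rng = np.random.default_rng([seed, 12])
    n_valid = 0
    results = []
    for inv in sim.truth.inversions:
        carrier_samples = sorted({s for s, _ in inv.carriers})[:3]
        pg = bpv.build_pangenome(sim.reference.seqs[inv.chrom], inv.pair, flank)
        attempts = []
        for sample in carrier_samples:
            reads = junction_reads(sim.reference, sim.truth, inv.pair,
                                   coverage, rng, cfg.read_model,
                                   samples=[(sample, 0), (sample, 1)],
                                   flank=flank)
            res = bpv.validate_inversion(bpv.assign_reads(reads, pg), null,
                                         inv.id)
            attempts.append(res)
            if res.overall_valid:
                break
        results.append(attempts)
        n_valid += any(a.overall_valid for a in attempts)
    return {"recall": n_valid / len(sim.truth.inversions),
            "n_inversions": len(sim.truth.inversions),
            "results": results, "null": null}


# ---------------------------------------------------------------------------
# introgression recovery
# ---------------------------------------------------------------------------

def _admixture_config(seed: int, fraction: float,
                      mean_tract: int = 500_000,
                      shared: bool = False,
                      min_tract: int = 0,
                      n_tracts: int | None = None) -> SimConfig:
    """A balanced four-colony quartet with one admixture event.

    Recovery experiments use equal founder counts (8) and four samples per
    colony so the realised admixture fraction concentrates around the
    configured value; inversions and repeats are irrelevant to the
    frequency statistics and are turned off.
    """
    events = ([AdmixtureEvent("Kenya_Aaf", "Kenya_Aaa", fraction, mean_tract,
                              shared=shared, min_tract=min_tract,
                              n_tracts=n_tracts)]
              if fraction > 0 else [])
    return SimConfig(
        seed=seed, repeat_density=0.0,
        colonies=[
            ColonySpec("USA_Aaa", "Aaa", 4, 8),
            ColonySpec("Kenya_Aaa", "Aaa", 4, 8),
            ColonySpec("Kenya_Aaf", "Aaf", 4, 8),
            ColonySpec("Mascarensis", "sister", 2, 8),
        ],
        admixture=events, inversions=[])


def introgression_recovery(seed: int, fraction: float,
                           window_size: int = 250_000,
                           block_size: int = 500_000,
                           shared: bool = False,
                           min_tract: int = 0,
                           n_tracts: int | None = None) -> dict:
    """Genome-wide D/Z and mean fD inside planted tracts at one admixture
    fraction (P1=USA_Aaa, P2=Kenya_Aaa, P3=Kenya_Aaf, O=Mascarensis)."""
    cfg = _admixture_config(seed, fraction, shared=shared,
                            min_tract=min_tract, n_tracts=n_tracts)
    sim = simulate_all(cfg)
    panel = sim.panel
    freqs = intro.quartet_frequencies(
        panel, panel.colony_samples("USA_Aaa"),
        panel.colony_samples("Kenya_Aaa"),
        panel.colony_samples("Kenya_Aaf"),
        panel.colony_samples("Mascarensis"))
    d = intro.patterson_d_jackknife(freqs, block_size)
    track = intro.martin_fd(freqs, cfg.chrom_lengths, window_size)
    tract_regions = recipient_tract_regions(sim.truth, "Kenya_Aaa")
    in_tract = _windows_overlapping(track, tract_regions)
    vals = track.values()
    tract_fd = (float(np.nanmean(vals[in_tract]))
                if in_tract.any() and np.isfinite(vals[in_tract]).any()
                else np.nan)
    return {"d": d.d, "z": float(d.z), "significant": d.significant,
            "tract_fd_mean": tract_fd, "track": track, "sim": sim}


def recipient_tract_regions(truth, colony_prefix: str
                            ) -> list[GenomicInterval]:
    """Merged union of planted tract intervals over a colony's haplotypes."""
    sub = truth.tracts[truth.tracts["sample"].str.startswith(colony_prefix)]
    merged: list[GenomicInterval] = []
    for chrom, grp in sub.groupby("chrom"):
        ivs = sorted((int(s), int(e)) for s, e in zip(grp["start"], grp["end"]))
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(str(chrom), cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append(GenomicInterval(str(chrom), cur_s, cur_e))
    return merged


def _windows_overlapping(track: intro.FDTrack,
                         regions: list[GenomicInterval]) -> np.ndarray:
    df = track.windows
    out = np.zeros(len(df), dtype=bool)
    for i, row in df.iterrows():
        w = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        out[i] = any(w.overlaps(r) for r in regions)
    return out


def peak_recovery(seed: int, n_tracts: int = 3, tract_length: int = 500_000,
                  window_size: int = 250_000,
                  local_window: int = 2_000_000) -> dict:
    """fD peak calling against planted high-frequency introgressed regions.

    Peaks are *localised* signals, so this experiment plants ``n_tracts``
    donor regions of ``tract_length`` carried by every recipient founder
    haplotype (a few percent of the genome). Recall = fraction of planted
    tract regions overlapped by a detected peak; the false-window rate is
    the fraction of non-tract windows belonging to a peak.
    """
    rec = introgression_recovery(seed, 0.05, window_size, shared=True,
                                 n_tracts=n_tracts)
    track, sim = rec["track"], rec["sim"]
    peaks = intro.detect_peaks(track, fence=1.5, local_window=local_window,
                               local_frac=0.9)
    regions = recipient_tract_regions(sim.truth, "Kenya_Aaa")
    hit = [any(p.interval.overlaps(r) for p in peaks) for r in regions]
    recall = float(np.mean(hit)) if regions else np.nan
    in_tract = _windows_overlapping(track, regions)
    in_peak = np.zeros(len(track.windows), dtype=bool)
    for i, row in track.windows.iterrows():
        w = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        in_peak[i] = any(w.overlaps(p.interval) for p in peaks)
    n_out = int((~in_tract).sum())
    false_rate = float((in_peak & ~in_tract).sum() / n_out) if n_out else 0.0
    return {"recall": recall, "false_window_rate": false_rate,
            "n_peaks": len(peaks), "n_tracts": len(regions)}


# ---------------------------------------------------------------------------
# phylogeny recovery
# ---------------------------------------------------------------------------

def clean_subspecies_config(seed: int) -> SimConfig:
    """A small, admixture-free study for subspecies-split recovery."""
    return SimConfig(
        seed=seed,
        chrom_lengths={"1": 1_000_000, "2": 1_000_000},
        repeat_density=0.0,
        colonies=[
            ColonySpec("USA_Aaa", "Aaa", 2, 4),
            ColonySpec("Thailand_Aaa", "Aaa", 1, 4),
            ColonySpec("Uganda_Aaf", "Aaf", 2, 4),
            ColonySpec("Gabon_Aaf", "Aaf", 1, 4),
            ColonySpec("Mascarensis", "sister", 1, 4),
        ],
        admixture=[], inversions=[])


def subspecies_bootstrap_support(seed: int, n_sites: int = 1_000,
                                 n_reps: int = 100) -> dict:
    """Bootstrap support (%) for the Aaa/Aaf split on clean generator data."""
    cfg = clean_subspecies_config(seed)
    sim = simulate_all(cfg)
    aln = phylo.representative_alignment(sim.panel, seed=seed)
    rng = np.random.default_rng([seed, 13])
    if aln.n_sites > n_sites:
        keep = np.sort(rng.choice(aln.n_sites, n_sites, replace=False))
        aln = phylo.SnpAlignment(aln.taxa, aln.matrix[:, keep])
    tree = phylo.bootstrap_support(aln, n_reps=n_reps, seed=seed)
    aaa = frozenset(t for t in aln.taxa if t.endswith("_Aaa"))
    aaf = frozenset(t for t in aln.taxa if t.endswith("_Aaf"))
    every = frozenset(aln.taxa)
    # the subspecies split, keyed by whichever side the tree stores
    candidates = {aaa, every - aaa, aaf, every - aaf}
    support = max((v for k, v in tree.supports.items() if k in candidates),
                  default=0.0)
    return {"support": support, "tree": tree,
            "splits": {str(k): v for k, v in tree.supports.items()}}
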