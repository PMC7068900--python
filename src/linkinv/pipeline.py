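"""End-to-end orchestration: simulate -> filter -> merge -> validate ->
popgen -> introgression -> phylogeny.

Each stage writes its artifacts into a run directory and is skipped on
resume when its primary output already exists. The stage graph consumes only
declared inputs plus the config, so a rerun on unchanged inputs reproduces
the summary byte for byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breakpoints as bpv
from . import introgression as intro
from . import phylogeny as phylo
from . import popgen
from .genomics_io import (FilterConfig, build_callsets, filter_sites,
                          read_metadata, read_vcf, write_metadata, write_vcf)
from .simulate import (SimConfig, junction_reads, simulate_all,
                       write_reference_fasta)
from .sv_merge import (InversionCall, calls_to_frame, candidates_to_frame,
                       classify_and_count, merge_candidates, read_candidates)
from .intervals import GenomicInterval


@dataclass
class PipelineConfig:
    """All pipeline parameters with their published defaults.

    Window/block sizes default to toy scale (the simulated genome is ~1/100
    of the real coordinate scale); full-scale values are noted per field.
    """

    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # external-input mode
    vcf: str | None = None
    metadata: str | None = None
    candidates: str | None = None

    merge_threshold: float = 0.95          # reciprocal overlap for merging
    flank: int = 10_000                    # junction flank F
    n_null: int = 200                      # artificial breakpoints (pairs)
    coverage: float = 30.0
    min_cov: int = 10                      # "under 10X coverage ... discarded"
    cov_fence: float = 2.0                 # "more than 2x the inter-quartile range"
    min_inv_frac: float = 0.37             # "more than 37% ... inverted"
    window_size: int = 250_000             # 1 Mb at full scale
    block_size: int = 500_000              # jackknife blocks; 5 Mb full scale
    local_window: int = 2_000_000          # fD peak locality; 200 Mb full scale
    fd_fence: float = 1.5
    fd_local_frac: float = 0.9
    aim_fst_min: float = 0.8
    n_bootstrap: int = 100
    quartet: tuple[str, str, str, str] = (
        "USA_Aaa", "Kenya_Aaa", "Kenya_Aaf", "Mascarensis")
    stages: tuple[str, ...] = ("simulate", "filter", "merge", "validate",
                               "popgen", "introgress", "phylo")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimConfig(**sim_raw)
        cfg.sim.seed = cfg.seed
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for label, p in (("vcf", self.vcf), ("metadata", self.metadata),
                             ("candidates", self.candidates)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"pipeline input {label!r} missing: {p}")


def run_pipeline(config: PipelineConfig, run_dir: str | Path,
                 resume: bool = False) -> dict:
    """Execute the configured stages; returns (and writes) the run summary."""
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    sim = None
    if config.simulate:
        sim = simulate_all(config.sim)
        if "simulate" in config.stages:
            meta_path = run_dir / "metadata.tsv"
            if not (resume and meta_path.exists()):
                write_reference_fasta(sim.reference,
                                      str(run_dir / "reference.fa"))
                write_vcf(sim.panel, str(run_dir / "panel.vcf"),
                          config.sim.chrom_lengths)
                write_metadata(sim.panel, str(meta_path))
                cand_rows = [candidates_to_frame(c)
                             for c in sim.candidates.values()]
                pd.concat(cand_rows).to_csv(run_dir / "candidates.tsv",
                                            sep="\t", index=False)
                sim.reference.repeats.to_csv(
                    run_dir / "repeats.bed", sep="\t", index=False, header=False)
        panel = sim.panel
        outgroups = sim.outgroup_panels
        candidates = [c for cl in sim.candidates.values() for c in cl]
        chrom_lengths = dict(config.sim.chrom_lengths)
    else:
        colony_of, role_of = read_metadata(config.metadata)
        panel = read_vcf(config.vcf, colony_of, role_of)
        outgroups = []
        candidates = read_candidates(config.candidates)
        chrom_lengths = {
            c: int(panel.sites.loc[panel.sites["chrom"] == c, "pos"].max())
            for c in pd.unique(panel.sites["chrom"])}

    # ---- filter / callsets ------------------------------------------------
    filtered = filter_sites(panel, FilterConfig())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        colony_cs, conserved_cs = build_callsets(filtered, outgroups)
    summary["n_sites_raw"] = panel.n_sites
    summary["n_sites_filtered"] = filtered.n_sites
    summary["n_sites_colony_callset"] = colony_cs.n_sites
    summary["n_sites_conserved_callset"] = conserved_cs.n_sites
    if "filter" in config.stages and not (
            resume and (run_dir / "colony_callset.vcf").exists()):
        write_vcf(colony_cs, str(run_dir / "colony_callset.vcf"), chrom_lengths)

    # ---- merge ------------------------------------------------------------
    calls = merge_candidates(candidates, threshold=config.merge_threshold)
    counts = classify_and_count(calls)
    summary["merge"] = counts
    if "merge" in config.stages:
        calls_to_frame(calls).to_csv(run_dir / "merged_calls.tsv",
                                     sep="\t", index=False)

    # ---- validate ---------------------------------------------------------
    if "validate" in config.stages and sim is not None:
        val = _validate_stage(config, sim, calls)
        val.to_csv(run_dir / "validation.tsv", sep="\t", index=False)
        summary["n_validated"] = int(val.loc[val["valid"], "inversion"].nunique())
        summary["null_false_validation_rate"] = float(
            val.attrs["null_false_validation_rate"])

    # ---- popgen -----------------------------------------------------------
    if "popgen" in config.stages:
        frames = []
        for colony in colony_cs.colonies():
            if len(colony_cs.colony_samples(colony)) < 2:
                continue
            frames.append(popgen.window_diversity(
                colony_cs, colony, chrom_lengths, config.window_size)
                .assign(colony=colony))
        windows = pd.concat(frames, ignore_index=True)
        windows.to_csv(run_dir / "diversity_windows.tsv", sep="\t", index=False)
        summary["pi_by_colony"] = {
            c: round(float(g["value"].mean()), 8)
            for c, g in windows.groupby("colony")}
        role = colony_cs.role_of
        pure_a = [c for c in colony_cs.colonies()
                  if role.get(c) == "Aaa" and "Kenya" not in c]
        pure_b = [c for c in colony_cs.colonies()
                  if role.get(c) == "Aaf" and "Kenya" not in c]
        aims = popgen.select_aims(colony_cs, conserved_cs, pure_a, pure_b,
                                  fst_min=config.aim_fst_min)
        pd.DataFrame([(a.chrom, a.pos, a.fst) for a in aims],
                     columns=["chrom", "pos", "fst"]).to_csv(
            run_dir / "aims.tsv", sep="\t", index=False)
        summary["n_aims"] = len(aims)

    # ---- introgression ----------------------------------------------------
    if "introgress" in config.stages:
        p1c, p2c, p3c, oc = config.quartet
        freqs = intro.quartet_frequencies(
            colony_cs, colony_cs.colony_samples(p1c),
            colony_cs.colony_samples(p2c), colony_cs.colony_samples(p3c),
            colony_cs.colony_samples(oc))
        d = intro.patterson_d_jackknife(freqs, config.block_size)
        summary["patterson_d"] = {
            "d": round(float(d.d), 6), "z": round(float(d.z), 4),
            "significant": bool(d.significant), "n_blocks": int(d.n_blocks)}
        track = intro.martin_fd(freqs, chrom_lengths, config.window_size)
        track.windows.to_csv(run_dir / "fd_track.tsv", sep="\t", index=False)
        peaks = intro.detect_peaks(track, config.fd_fence,
                                   config.local_window, config.fd_local_frac)
        with open(run_dir / "fd_peaks.bed", "w") as fh:
            for p in peaks:
                fh.write(f"{p.interval.chrom}\t{p.interval.start}"
                         f"\t{p.interval.end}\t{p.max_fd:.4f}\n")
        summary["n_fd_peaks"] = len(peaks)

    # ---- phylogeny --------------------------------------------------------
    if "phylo" in config.stages:
        aln = phylo.representative_alignment(colony_cs, seed=config.seed)
        aln = _subsample_taxa(aln, colony_cs)
        tree = phylo.bootstrap_support(aln, n_reps=config.n_bootstrap,
                                       seed=config.seed)
        (run_dir / "genome_tree.nwk").write_text(
            tree.newick(include_support=True) + "\n")
        summary["tree_score"] = float(tree.score)

    out = json.dumps(summary, indent=2, sort_keys=True)
    (run_dir / "summary.json").write_text(out + "\n")
    return summary


def _subsample_taxa(aln, panel, per_colony: int = 1, max_sites: int = 1_000):
    """One representative taxon per colony (and a site cap) keeps the
    genome-tree search cheap; taxa align with ``panel.samples`` order."""
    keep, seen = [], {}
    for i, sample in enumerate(panel.samples):
        colony = panel.colony_of[sample]
        if seen.get(colony, 0) < per_colony:
            seen[colony] = seen.get(colony, 0) + 1
            keep.append(i)
    matrix = aln.matrix[np.array(keep)]
    if matrix.shape[1] > max_sites:
        idx = np.linspace(0, matrix.shape[1] - 1, max_sites).astype(int)
        matrix = matrix[:, idx]
    return phylo.SnpAlignment([aln.taxa[i] for i in keep], matrix)


def _validate_stage(config: PipelineConfig, sim, calls: list[InversionCall]
                    ) -> pd.DataFrame:
    """Null calibration plus per-call long-read validation on synthetic reads."""
    rng = np.random.default_rng([config.seed, 5])
    ref = sim.reference
    model = config.sim.read_model
    pairs = [bpv.BreakpointPair(c.id, c.interval.chrom, *c.breakpoints())
             for c in calls]
    null_pairs = bpv.generate_artificial_breakpoints(
        ref.seqs, ref.repeats, pairs or [t.pair for t in sim.truth.inversions],
        n=config.n_null, seed=config.seed, flank=config.flank)
    null_assignments = []
    for pair in null_pairs:
        reads = junction_reads(ref, sim.truth, pair, config.coverage, rng,
                               model, samples=None, flank=config.flank)
        pg = bpv.build_pangenome(ref.seqs[pair.chrom], pair, config.flank)
        null_assignments.append(bpv.assign_reads(reads, pg))
    null = bpv.calibrate_null(null_assignments)

    rows = []
    for call, pair in zip(calls, pairs):
        samples = sorted(call.samples)[:2]
        sources = [(s, k) for s in samples for k in (0, 1)]
        reads = junction_reads(ref, sim.truth, pair, config.coverage, rng,
                               model, samples=sources, flank=config.flank)
        pg = bpv.build_pangenome(ref.seqs[pair.chrom], pair, config.flank)
        res = bpv.validate_inversion(
            bpv.assign_reads(reads, pg), null, call.id,
            config.min_cov, config.cov_fence, config.min_inv_frac)
        for bp in ("bp1", "bp2"):
            d = res.breakpoints[bp]
            rows.append({
                "inversion": call.id, "breakpoint": bp,
                "coverage": d.coverage, "inv_fraction": round(d.inverted_fraction, 4),
                "pass": d.passes, "reason": d.reason,
                "valid": res.overall_valid, "method": res.method})
    df = pd.DataFrame(rows)
    df.attrs["null_false_validation_rate"] = null.false_validation_rate(
        config.min_cov, config.cov_fence, config.min_inv_frac)
    return df
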