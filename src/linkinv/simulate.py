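"""Synthetic colony data with known ground truth.

The generator emulates, at toy scale (three 5-Mb chromosomes, ~1/100 of the
real coordinate scale), the data underlying a linked-read inversion and
introgression study of *Aedes aegypti* colonies:

* a repeat-dense reference (default 30% planted repeat arrays, echoing a
  genome two-thirds of which is repetitive);
* biallelic SNP panels for colonies drawn from two diverged subspecies
  (``Aaa``/``Aaf``), a hybrid colony, a sister-species colony, and two
  distant outgroup species — divergence via Balding-Nichols drift, colony
  founder effects via resampling of a small founder-haplotype pool;
* introgressed tracts copied from donor into recipient haplotypes at a
  configured admixture fraction, with tract intervals recorded as truth;
* inversions spiked at known colony frequencies (micro and large),
  realised as reverse-complemented haplotype segments;
* Nanopore-like long reads (configurable N50, default 6789 bp; substitution
  errors) and two caller-like candidate sets with different size profiles,
  breakpoint jitter, and repeat-seeking false positives.

Every output is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .align import revcomp
from .breakpoints import BreakpointPair
from .genomics_io import GenotypePanel
from .intervals import GenomicInterval
from .sv_merge import InversionCandidate, MICRO_MAX_BP

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[a] = b


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ColonySpec:
    name: str
    subspecies: str      # "Aaa" | "Aaf" | "hybrid" | "sister"
    n_samples: int = 3
    n_founders: int = 6


@dataclass
class AdmixtureEvent:
    donor: str
    recipient: str
    fraction: float
    mean_tract: int = 400_000
    #: shared=True plants one tract set carried by *every* recipient founder
    #: haplotype (a high-frequency introgressed region, the signal an fD peak
    #: scan looks for); False gives independent tracts per founder haplotype.
    shared: bool = False
    #: lower bound on tract length (lengths are min_tract + exponential)
    min_tract: int = 0
    #: plant exactly this many tracts of length ``mean_tract`` at random
    #: non-overlapping positions instead of the stationary renewal process
    #: (``fraction`` is then ignored); for controlled recovery experiments.
    n_tracts: int | None = None


@dataclass
class InversionSpec:
    id: str
    size: int
    #: colony -> carrier haplotype frequency
    frequencies: dict[str, float] = field(default_factory=dict)
    #: place the locus inside a repeat array (a deliberate hard case)
    at_repeat: bool = False


@dataclass
class ReadModel:
    n50: int = 6789
    sigma: float = 0.55
    error_rate: float = 0.05
    min_length: int = 200


@dataclass
class CallerProfile:
    name: str
    sens_micro: float = 0.9
    sens_large: float = 0.55
    jitter_sd: float = 30.0
    n_false_positives: int = 20
    fp_log10_size: tuple[float, float] = (4.0, 5.3)


@dataclass
class SimConfig:
    """Full description of a synthetic study; seed determines every byte."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 5_000_000, "2": 5_000_000, "3": 5_000_000})
    repeat_density: float = 0.30
    repeat_motif_lengths: tuple[int, ...] = (300, 1_200, 4_000)
    snp_rate: float = 1 / 500
    #: Balding-Nichols drift of each subspecies pool from the ancestor
    f_split: dict[str, float] = field(default_factory=lambda: {
        "Aaa": 0.25, "Aaf": 0.12, "sister": 0.45})
    f_outgroup: float = 0.85
    mutation_rate: float = 5e-4
    missing_rate: float = 0.01
    low_quality_rate: float = 0.03
    colonies: list[ColonySpec] = field(default_factory=lambda: [
        ColonySpec("USA_Aaa", "Aaa", 3, 4),
        ColonySpec("Thailand_Aaa", "Aaa", 3, 6),
        ColonySpec("Kenya_Aaa", "Aaa", 3, 3),
        ColonySpec("Kenya_Hyb", "hybrid", 3, 2),
        ColonySpec("Kenya_Aaf", "Aaf", 3, 9),
        ColonySpec("Uganda_Aaf", "Aaf", 3, 8),
        ColonySpec("Gabon_Aaf", "Aaf", 3, 6),
        ColonySpec("Mascarensis", "sister", 2, 10),
    ])
    outgroup_species: tuple[str, ...] = ("Albopictus", "Bromeliae")
    admixture: list[AdmixtureEvent] = field(default_factory=lambda: [
        AdmixtureEvent("Kenya_Aaf", "Kenya_Aaa", 0.30),
        AdmixtureEvent("Kenya_Aaf", "Kenya_Hyb", 0.35),
        AdmixtureEvent("Kenya_Aaa", "Kenya_Aaf", 0.13),
    ])
    inversions: list[InversionSpec] = field(default_factory=lambda: [
        InversionSpec("inv_a", 35_000, {"USA_Aaa": 0.5, "Kenya_Aaa": 0.3}),
        InversionSpec("inv_b", 60_000, {"Kenya_Aaf": 0.5, "Kenya_Hyb": 0.5}),
        InversionSpec("inv_c", 120_000, {"Uganda_Aaf": 1.0}),
        InversionSpec("inv_d", 45_000, {"Thailand_Aaa": 0.5, "Gabon_Aaf": 0.3}),
        InversionSpec("inv_e", 200_000, {"Kenya_Hyb": 0.3, "Mascarensis": 0.5}),
        InversionSpec("inv_f", 90_000, {"Gabon_Aaf": 0.5}),
        InversionSpec("inv_g", 1_200_000, {"USA_Aaa": 0.3, "Uganda_Aaf": 0.3}),
        InversionSpec("inv_h", 2_000_000, {"Kenya_Aaf": 0.5}),
    ])
    inversion_flank: int = 10_000
    read_model: ReadModel = field(default_factory=ReadModel)
    callers: list[CallerProfile] = field(default_factory=lambda: [
        CallerProfile("LR", sens_micro=0.9, sens_large=0.45, jitter_sd=30,
                      n_false_positives=20, fp_log10_size=(4.0, 5.3)),
        CallerProfile("GSV", sens_micro=0.35, sens_large=0.9, jitter_sd=80,
                      n_false_positives=6, fp_log10_size=(5.0, 6.5)),
    ])

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TrueInversion:
    id: str
    chrom: str
    start: int
    end: int
    carriers: list[tuple[str, int]]  # (sample, haplotype index)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def pair(self) -> BreakpointPair:
        return BreakpointPair(self.id, self.chrom, self.start, self.end)

    @property
    def is_micro(self) -> bool:
        return self.end - self.start < MICRO_MAX_BP


@dataclass
class SyntheticTruth:
    inversions: list[TrueInversion] = field(default_factory=list)
    #: columns sample, hap, chrom, start, end, donor
    tracts: pd.DataFrame = field(default_factory=pd.DataFrame)
    founder_of: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)
    ancestral_freq: np.ndarray | None = None

    def carriers_of(self, inversion_id: str) -> list[tuple[str, int]]:
        for inv in self.inversions:
            if inv.id == inversion_id:
                return inv.carriers
        raise KeyError(inversion_id)


@dataclass
class Reference:
    seqs: dict[str, str]
    repeats: pd.DataFrame  # chrom, start, end, family

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(config: SimConfig) -> Reference:
    """Random reference with planted tandem-repeat arrays.

    Arrays of each family's motif are overwritten onto the background until
    the masked fraction reaches ``repeat_density``; the annotation records
    every planted array. Deterministic under the config seed.
    """
    if config.repeat_density > 1:
        raise ValueError("repeat density must be <= 1")
    rng = np.random.default_rng([config.seed, 1])
    motifs = [rng.integers(0, 4, size=m) for m in config.repeat_motif_lengths]
    seqs: dict[str, str] = {}
    rows = []
    for chrom, length in config.chrom_lengths.items():
        arr = _BASES[rng.integers(0, 4, size=length)]
        if config.repeat_density > 0:
            mask = np.zeros(length, dtype=bool)
            while mask.mean() < config.repeat_density:
                fam = int(rng.integers(len(motifs)))
                copies = int(rng.integers(2, 7))
                unit = _BASES[np.tile(motifs[fam], copies)]
                start = int(rng.integers(0, length - len(unit)))
                arr[start:start + len(unit)] = unit
                mask[start:start + len(unit)] = True
                rows.append((chrom, start, start + len(unit), f"fam{fam}"))
        seqs[chrom] = arr.tobytes().decode()
    repeats = pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])
    return Reference(seqs=seqs, repeats=repeats)


def repeat_mask_fraction(reference: Reference, chrom: str,
                         start: int, end: int) -> float:
    mask = np.zeros(reference.length(chrom), dtype=bool)
    sub = reference.repeats[reference.repeats["chrom"] == chrom]
    for r in sub.itertuples():
        mask[int(r.start):int(r.end)] = True
    return float(mask[start:end].mean())


# ---------------------------------------------------------------------------
# genotype panel simulation
# ---------------------------------------------------------------------------

def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def simulate_panel(config: SimConfig, reference: Reference
                   ) -> tuple[GenotypePanel, list[GenotypePanel], SyntheticTruth]:
    """Simulate the colony panel, outgroup species panels, and truth.

    Ancestral alt-allele frequencies are drawn per site; each subspecies
    pool drifts by Balding-Nichols with its ``f_split``; colony haplotypes
    are copies (with low-rate mutation) of a small founder-haplotype pool,
    which produces founder effects and long shared haplotypes; admixture
    events then copy donor tracts into recipient haplotypes. The returned
    colony panel is phased (haplotype-resolved by construction).
    """
    rng = np.random.default_rng([config.seed, 2])
    sites_frames = []
    for chrom, length in config.chrom_lengths.items():
        n = int(length * config.snp_rate)
        pos0 = np.sort(rng.choice(length, size=n, replace=False))
        refb = np.frombuffer(reference.seqs[chrom].encode(), dtype=np.uint8)[pos0]
        shift = rng.integers(1, 4, size=n)
        altb = _BASES[(np.searchsorted(_BASES, refb) + shift) % 4]
        sites_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos0 + 1,
            "ref": [chr(b) for b in refb], "alt": [chr(b) for b in altb]}))
    sites = pd.concat(sites_frames, ignore_index=True)
    n_sites = len(sites)

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    pool_freq = {sub: _balding_nichols(rng, p_anc, f)
                 for sub, f in config.f_split.items()}

    truth = SyntheticTruth(ancestral_freq=p_anc)
    founder_store: dict[str, np.ndarray] = {}  # colony -> (n_sites, 2*n_founders)
    samples: list[str] = []
    colony_of: dict[str, str] = {}
    role_of: dict[str, str] = {}

    for colony in config.colonies:
        role_of[colony.name] = colony.subspecies
        n_f = 2 * colony.n_founders
        if colony.subspecies == "hybrid":
            half = n_f // 2
            founders = np.concatenate([
                (rng.random((n_sites, half)) < pool_freq["Aaa"][:, None]),
                (rng.random((n_sites, n_f - half)) < pool_freq["Aaf"][:, None]),
            ], axis=1)
        else:
            founders = (rng.random((n_sites, n_f))
                        < pool_freq[colony.subspecies][:, None])
        founder_store[colony.name] = founders.astype(np.int8)

    # admixture is applied to *founder* haplotypes (colony founders were
    # sampled from a population that already carried introgressed tracts),
    # so tracts are shared by every colony haplotype copying that founder.
    chrom_arr = sites["chrom"].to_numpy()
    pos0_arr = sites["pos"].to_numpy() - 1
    pristine = {c: f.copy() for c, f in founder_store.items()}
    founder_tracts: dict[tuple[str, int], list[tuple[str, int, int, str]]] = {}
    def _draw_tracts(event) -> list[tuple[str, int, int]]:
        chrom_names = list(config.chrom_lengths)
        if event.n_tracts is not None:
            placed: list[tuple[str, int, int]] = []
            while len(placed) < event.n_tracts:
                # round-robin over chromosomes keeps planted signals apart
                chrom = chrom_names[len(placed) % len(chrom_names)]
                length = config.chrom_lengths[chrom]
                s = int(rng.integers(0, max(1, length - event.mean_tract)))
                e = s + event.mean_tract
                if all(c != chrom or e <= ps or s >= pe
                       for c, ps, pe in placed):
                    placed.append((chrom, s, e))
            return sorted(placed)
        gap_mean = event.mean_tract * (1 - event.fraction) / event.fraction
        tracts = []
        for chrom, length in config.chrom_lengths.items():
            cursor = 0
            while cursor < length:
                cursor += int(rng.exponential(gap_mean)) + 1
                if cursor >= length:
                    break
                t_len = event.min_tract + int(rng.exponential(
                    max(event.mean_tract - event.min_tract, 1))) + 1
                t_end = min(cursor + t_len, length)
                tracts.append((chrom, cursor, t_end))
                cursor = t_end
        return tracts

    for event in config.admixture:
        if event.fraction <= 0:
            continue
        donor_haps = pristine[event.donor]
        rec = founder_store[event.recipient]
        shared_tracts = _draw_tracts(event) if event.shared else None
        for col in range(rec.shape[1]):
            tracts = shared_tracts if event.shared else _draw_tracts(event)
            for chrom, t_start, t_end in tracts:
                sel = ((chrom_arr == chrom) & (pos0_arr >= t_start)
                       & (pos0_arr < t_end))
                d_col = int(rng.integers(donor_haps.shape[1]))
                rec[sel, col] = donor_haps[sel, d_col]
                founder_tracts.setdefault((event.recipient, col), []).append(
                    (chrom, t_start, t_end, event.donor))

    # resample colony haplotypes from the founder pool (founder effect)
    tract_rows = []
    genotype_cols = []
    for colony in config.colonies:
        founders = founder_store[colony.name]
        n_f = founders.shape[1]
        for i in range(colony.n_samples):
            sample = f"{colony.name}_{i + 1}"
            samples.append(sample)
            colony_of[sample] = colony.name
            pair = np.empty((n_sites, 2), dtype=np.int8)
            for k in (0, 1):
                fidx = int(rng.integers(n_f))
                hap = founders[:, fidx].copy()
                flips = rng.random(n_sites) < config.mutation_rate
                hap[flips] = 1 - hap[flips]
                pair[:, k] = hap
                truth.founder_of[(sample, k)] = (colony.name, fidx)
                for chrom, t_start, t_end, donor in founder_tracts.get(
                        (colony.name, fidx), []):
                    tract_rows.append((sample, k, chrom, t_start, t_end, donor))
            genotype_cols.append(pair)
    truth.tracts = pd.DataFrame(
        tract_rows, columns=["sample", "hap", "chrom", "start", "end", "donor"])

    genotypes = np.stack(genotype_cols, axis=1)

    if config.missing_rate > 0:
        miss = rng.random((n_sites, len(samples))) < config.missing_rate
        genotypes[miss] = -1

    # GATK-like annotations, with a low-quality contaminant fraction
    qd = rng.uniform(8, 35, size=n_sites)
    fs = np.minimum(rng.exponential(5, size=n_sites), 55.0)
    ranksum = rng.normal(0, 1.5, size=n_sites)
    bad = rng.random(n_sites) < config.low_quality_rate
    which = rng.integers(0, 3, size=n_sites)
    qd[bad & (which == 0)] = rng.uniform(0, 5, size=int((bad & (which == 0)).sum()))
    fs[bad & (which == 1)] = rng.uniform(60, 120, size=int((bad & (which == 1)).sum()))
    ranksum[bad & (which == 2)] = rng.choice([-1, 1], size=int(
        (bad & (which == 2)).sum())) * rng.uniform(8, 15, size=int(
            (bad & (which == 2)).sum()))
    # two decimals: survives VCF text serialisation (%.6g) exactly
    sites["qd"] = np.round(qd, 2).astype(np.float32)
    sites["fs"] = np.round(fs, 2).astype(np.float32)
    sites["ranksum"] = np.round(ranksum, 2).astype(np.float32)

    panel = GenotypePanel(sites=sites.copy(), genotypes=genotypes,
                          samples=samples, colony_of=colony_of,
                          role_of=role_of, phased=True)

    outgroup_panels = []
    for species in config.outgroup_species:
        p_o = _balding_nichols(rng, p_anc, config.f_outgroup)
        g = (rng.random((n_sites, 1, 2)) < p_o[:, None, None]).astype(np.int8)
        outgroup_panels.append(GenotypePanel(
            sites=sites.copy(), genotypes=g, samples=[f"{species}_1"],
            colony_of={f"{species}_1": species},
            role_of={species: "outgroup"}, phased=False))
    return panel, outgroup_panels, truth


# ---------------------------------------------------------------------------
# inversions
# ---------------------------------------------------------------------------

def spike_inversions(config: SimConfig, reference: Reference,
                     panel: GenotypePanel, truth: SyntheticTruth) -> None:
    """Place configured inversions and assign carrier haplotypes in truth.

    Clean loci require both breakpoint flanks to be < 10% repeat; loci with
    ``at_repeat`` require > 50%. Placed loci (including flanks) do not
    overlap each other. Carriers are drawn per colony as Bernoulli(freq) per
    haplotype; every inversion is guaranteed >= 1 carrier haplotype.
    """
    rng = np.random.default_rng([config.seed, 3])
    flank = config.inversion_flank
    masks = {}
    for chrom in config.chrom_lengths:
        m = np.zeros(reference.length(chrom), dtype=bool)
        for r in reference.repeats[reference.repeats["chrom"] == chrom].itertuples():
            m[int(r.start):int(r.end)] = True
        masks[chrom] = np.concatenate([[0], np.cumsum(m, dtype=np.int64)])
    placed: list[GenomicInterval] = []
    chroms = list(config.chrom_lengths)
    for spec in config.inversions:
        for _ in range(5000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = reference.length(chrom)
            if length < spec.size + 4 * flank:
                continue
            s = int(rng.integers(2 * flank, length - spec.size - 2 * flank))
            e = s + spec.size
            cs = masks[chrom]
            fr1 = (cs[s + flank] - cs[s - flank]) / (2 * flank)
            fr2 = (cs[e + flank] - cs[e - flank]) / (2 * flank)
            ok = (min(fr1, fr2) > 0.5 if spec.at_repeat
                  else max(fr1, fr2) < 0.10)
            iv = GenomicInterval(chrom, s - 2 * flank, e + 2 * flank)
            if ok and not any(iv.overlaps(p) for p in placed):
                placed.append(iv)
                break
        else:
            raise RuntimeError(f"could not place inversion {spec.id}")
        carriers = []
        for colony_name, freq in spec.frequencies.items():
            for sample in panel.colony_samples(colony_name):
                for k in (0, 1):
                    if rng.random() < freq:
                        carriers.append((sample, k))
        if not carriers:
            pool = [(s_, k) for c, f in spec.frequencies.items() if f > 0
                    for s_ in panel.colony_samples(c) for k in (0, 1)]
            carriers = [pool[int(rng.integers(len(pool)))]]
        truth.inversions.append(TrueInversion(spec.id, chrom, s, e, carriers))


def haplotype_sequence(reference: Reference, truth: SyntheticTruth,
                       sample: str, hap: int, chrom: str) -> str:
    """Chromosome sequence of one haplotype: the reference with every carried
    inversion's segment reverse-complemented (coordinates are preserved
    because inversion is length-neutral)."""
    arr = np.frombuffer(reference.seqs[chrom].encode(), dtype=np.uint8).copy()
    for inv in truth.inversions:
        if inv.chrom == chrom and (sample, hap) in inv.carriers:
            seg = arr[inv.start:inv.end]
            arr[inv.start:inv.end] = _COMP_TABLE[seg[::-1]]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def simulate_long_reads(seq: str, coverage: float, rng,
                        model: ReadModel | None = None,
                        window: tuple[int, int] | None = None,
                        id_prefix: str = "read",
                        count_min_length: int = 0) -> list[tuple[str, str]]:
    """Sample long reads from ``seq`` at the requested mean coverage.

    Lengths are log-normal with the scale chosen so the length-weighted
    median (N50) matches ``model.n50`` (for a log-normal the length-biased
    distribution is again log-normal, so ``mu = ln(N50) - sigma^2``). Starts
    are uniform over ``window`` (default: the whole sequence); per-base
    substitution errors at ``model.error_rate``; strand random, with the
    reverse-complement emitted for minus-strand reads.

    ``count_min_length`` restricts which reads count toward the coverage
    target: downstream validation selects only the longest reads, so a
    positive value (e.g. 5000) makes ``coverage`` the coverage *in selected
    reads* while shorter reads are still emitted alongside.
    """
    model = model or ReadModel()
    a, b = window if window is not None else (0, len(seq))
    target_bases = coverage * (b - a)
    if target_bases <= 0:
        return []
    mu = np.log(model.n50) - model.sigma ** 2
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    reads = []
    total = 0
    i = 0
    while total < target_bases:
        length = max(model.min_length,
                     int(rng.lognormal(mu, model.sigma)))
        start = int(rng.integers(max(0, a - length + 1), b))
        end = min(start + length, len(arr))
        if end - start < model.min_length:
            continue
        read = arr[start:end].copy()
        if model.error_rate > 0:
            errs = np.flatnonzero(rng.random(len(read)) < model.error_rate)
            if len(errs):
                shift = rng.integers(1, 4, size=len(errs))
                read[errs] = _BASES[(np.searchsorted(_BASES, read[errs])
                                     + shift) % 4]
        strand = "+"
        if rng.random() < 0.5:
            read = _COMP_TABLE[read[::-1]]
            strand = "-"
        reads.append((f"{id_prefix}_{i}{strand}", read.tobytes().decode()))
        if end - start >= count_min_length:
            total += end - start
        i += 1
    return reads


def realized_n50(lengths) -> int:
    """Length-weighted median of a read-length set."""
    ls = np.sort(np.asarray(lengths))[::-1]
    half = ls.sum() / 2
    return int(ls[np.searchsorted(np.cumsum(ls), half)])


def junction_reads(reference: Reference, truth: SyntheticTruth,
                   pair: BreakpointPair, coverage: float, rng,
                   model: ReadModel | None = None,
                   samples: list[tuple[str, int]] | None = None,
                   pad: int = 2_000, flank: int = 10_000,
                   count_min_length: int = 5_000
                   ) -> list[tuple[str, str]]:
    """Reads covering both junction neighbourhoods of a breakpoint pair.

    ``samples`` lists the (sample, haplotype) sequences reads derive from;
    ``None`` simulates from the plain reference (the uninverted null case).
    Coverage is split evenly across the source haplotypes and, mirroring
    the longest-read selection step, is measured in reads longer than
    ``count_min_length``.
    """
    model = model or ReadModel()
    sources: list[str]
    if samples is None:
        sources = [reference.seqs[pair.chrom]]
    else:
        sources = [haplotype_sequence(reference, truth, s, k, pair.chrom)
                   for s, k in samples]
    span = flank + pad
    reads = []
    for si, seq in enumerate(sources):
        per = coverage / len(sources)
        for bi, bp in enumerate((pair.bp1, pair.bp2)):
            w = (max(0, bp - span), min(len(seq), bp + span))
            reads.extend(simulate_long_reads(
                seq, per, rng, model, window=w,
                id_prefix=f"{pair.inversion_id}_s{si}_b{bi}",
                count_min_length=count_min_length))
    return reads


# ---------------------------------------------------------------------------
# caller-like candidates
# ---------------------------------------------------------------------------

def simulate_candidate_calls(config: SimConfig, reference: Reference,
                             truth: SyntheticTruth
                             ) -> dict[str, list[InversionCandidate]]:
    """Emit per-caller candidate lists from the truth.

    Each caller detects a carrier sample's inversion with a size-class
    sensitivity, jitters breakpoints (Gaussian, caller-specific SD), and adds
    false positives centred on planted repeat arrays with a caller-specific
    size profile.
    """
    rng = np.random.default_rng([config.seed, 4])
    out: dict[str, list[InversionCandidate]] = {}
    rep = reference.repeats
    for caller in config.callers:
        cands: list[InversionCandidate] = []
        for inv in truth.inversions:
            sens = caller.sens_micro if inv.is_micro else caller.sens_large
            for sample in sorted({s for s, _ in inv.carriers}):
                if rng.random() >= sens:
                    continue
                js = int(round(rng.normal(0, caller.jitter_sd)))
                je = int(round(rng.normal(0, caller.jitter_sd)))
                start = max(0, inv.start + js)
                end = min(reference.length(inv.chrom), inv.end + je)
                if end <= start:
                    continue
                cands.append(InversionCandidate(
                    GenomicInterval(inv.chrom, start, end), sample, caller.name))
        all_samples = sorted({s for i in truth.inversions
                              for s, _ in i.carriers}) or ["sample_0"]
        chroms = list(reference.seqs)
        for _ in range(caller.n_false_positives):
            size = int(10 ** rng.uniform(*caller.fp_log10_size))
            if len(rep):
                row = rep.iloc[int(rng.integers(len(rep)))]
                chrom = str(row["chrom"])
                mid = int((row["start"] + row["end"]) // 2)
            else:  # no repeat annotation: false positives anywhere
                chrom = chroms[int(rng.integers(len(chroms)))]
                mid = int(rng.integers(reference.length(chrom)))
            length = reference.length(chrom)
            start = max(0, min(mid - size // 2, length - size - 1))
            end = min(length, start + size)
            sample = all_samples[int(rng.integers(len(all_samples)))]
            cands.append(InversionCandidate(
                GenomicInterval(chrom, start, end), sample, caller.name))
        out[caller.name] = cands
    return out


# ---------------------------------------------------------------------------
# sequence file output
# ---------------------------------------------------------------------------

def write_reference_fasta(reference: Reference, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in reference.seqs.items()]
    SeqIO.write(records, path, "fasta")


def write_reads_fastq(reads: list[tuple[str, str]], path: str,
                      quality: int = 20) -> None:
    """Write simulated reads as FASTQ with a flat Phred quality."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    reference: Reference
    panel: GenotypePanel
    outgroup_panels: list[GenotypePanel]
    truth: SyntheticTruth
    candidates: dict[str, list[InversionCandidate]]


def simulate_all(config: SimConfig) -> SimResult:
    """Run every generator stage for one config."""
    reference = simulate_reference(config)
    panel, outgroups, truth = simulate_panel(config, reference)
    spike_inversions(config, reference, panel, truth)
    candidates = simulate_candidate_calls(config, reference, truth)
    return SimResult(config=config, reference=reference, panel=panel,
                     outgroup_panels=outgroups, truth=truth,
                     candidates=candidates)
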