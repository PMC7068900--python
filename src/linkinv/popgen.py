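"""Windowed diversity/divergence statistics, ROH masking, AIMs, and
founder-haplotype clustering.

Conventions: nucleotide diversity pi uses the unbiased per-site estimator
``2 p (1-p) n/(n-1)`` summed over sites and divided by the *window length*
(1 Mb by default), matching the windowed convention of the standard VCF
toolchain; Weir & Cockerham's (1984) theta is the F_st estimator, with
windowed values formed as the ratio of summed variance components.
Ancestry-informative markers (AIMs) are sites with pooled-subspecies
F_st > 0.8 that are callable in both analysis callsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_io import GenotypePanel
from .intervals import GenomicInterval, make_windows


# ---------------------------------------------------------------------------
# windowed diversity
# ---------------------------------------------------------------------------

def _window_frame(windows, values, n_sites, statistic):
    return pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "stat": statistic,
        "value": values,
        "n_sites": n_sites,
    })


def _site_window_index(sites: pd.DataFrame, windows: list[GenomicInterval]
                       ) -> np.ndarray:
    """Window index for each site (-1 if none). Windows must tile chromosomes."""
    idx = np.full(len(sites), -1, dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    pos0 = sites["pos"].to_numpy() - 1  # sites are 1-based
    for chrom, widx in by_chrom.items():
        starts = np.array([windows[i].start for i in widx])
        ends = np.array([windows[i].end for i in widx])
        in_chrom = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        j = np.searchsorted(starts, pos0[in_chrom], side="right") - 1
        ok = (j >= 0) & (pos0[in_chrom] < ends[np.clip(j, 0, len(ends) - 1)])
        idx[in_chrom[ok]] = np.array(widx)[j[ok]]
    return idx


def window_diversity(panel: GenotypePanel, colony: str,
                     chrom_lengths: dict[str, int],
                     window_size: int = 1_000_000,
                     roh_mask: list[GenomicInterval] | None = None,
                     per_callable_site: bool = False) -> pd.DataFrame:
    """Windowed nucleotide diversity pi for one colony.

    Sites falling inside ``roh_mask`` intervals are excluded before summing
    (long runs of homozygosity reflect colony inbreeding, not population
    diversity). With ``per_callable_site`` the denominator is the number of
    contributing sites instead of the window length.
    """
    samples = panel.colony_samples(colony)
    if not samples:
        raise ValueError(f"unknown or empty colony {colony!r}")
    if len(samples) < 2:
        raise ValueError(f"colony {colony!r} has fewer than 2 samples")
    alt, n = panel.allele_counts(samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(n, 1)
        site_pi = np.where(n >= 2, 2.0 * p * (1 - p) * n / np.maximum(n - 1, 1), 0.0)

    keep = np.ones(panel.n_sites, dtype=bool)
    if roh_mask:
        pos0 = panel.sites["pos"].to_numpy() - 1
        chroms = panel.sites["chrom"].to_numpy()
        for iv in roh_mask:
            keep &= ~((chroms == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end))
    contributing = keep & (n >= 2)

    windows = make_windows(chrom_lengths, window_size)
    widx = _site_window_index(panel.sites, windows)
    values = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=int)
    sel = contributing & (widx >= 0)
    np.add.at(values, widx[sel], site_pi[sel])
    np.add.at(counts, widx[sel], 1)
    denom = (np.maximum(counts, 1) if per_callable_site
             else np.array([w.length for w in windows]))
    return _window_frame(windows, values / denom, counts, "pi")


def window_heterozygosity(panel: GenotypePanel, sample: str,
                          chrom_lengths: dict[str, int],
                          window_size: int = 1_000_000) -> pd.DataFrame:
    """Per-window heterozygous-call density (per bp) for one sample."""
    j = panel.sample_indices([sample])[0]
    g = panel.genotypes[:, j, :]
    het = (g[:, 0] >= 0) & (g[:, 1] >= 0) & (g[:, 0] != g[:, 1])
    windows = make_windows(chrom_lengths, window_size)
    widx = _site_window_index(panel.sites, windows)
    values = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=int)
    sel = widx >= 0
    np.add.at(values, widx[sel], het[sel].astype(float))
    np.add.at(counts, widx[sel], 1)
    return _window_frame(
        windows, values / np.array([w.length for w in windows]), counts, "het")


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

def detect_roh(panel: GenotypePanel, sample: str, chrom: str,
               min_length: int = 1_000_000,
               max_het_per_mb: float = 5.0,
               chrom_length: int | None = None) -> list[GenomicInterval]:
    """Density-scan detection of long runs of homozygosity.

    Windows of ``min_length`` (stepped at a tenth of the window) whose
    heterozygous-call density is <= ``max_het_per_mb`` (boundary included)
    are merged into maximal intervals. Intended to flag the long homozygous
    blocks produced by inbreeding.
    """
    j = panel.sample_indices([sample])[0]
    on_chrom = (panel.sites["chrom"] == chrom).to_numpy()
    g = panel.genotypes[on_chrom][:, j, :]
    pos0 = panel.sites.loc[on_chrom, "pos"].to_numpy() - 1
    het_pos = pos0[(g[:, 0] >= 0) & (g[:, 1] >= 0) & (g[:, 0] != g[:, 1])]
    if chrom_length is None:
        chrom_length = int(pos0.max()) + 1 if len(pos0) else 0
    if chrom_length < min_length:
        return []
    step = max(min_length // 10, 1)
    starts = np.arange(0, chrom_length - min_length + 1, step)
    n_het = (np.searchsorted(het_pos, starts + min_length)
             - np.searchsorted(het_pos, starts))
    density = n_het / (min_length / 1e6)
    passing = density <= max_het_per_mb
    out: list[GenomicInterval] = []
    run_start = None
    for s, ok in zip(starts, passing):
        if ok and run_start is None:
            run_start = s
        elif not ok and run_start is not None:
            out.append(GenomicInterval(chrom, int(run_start), int(s - step + min_length)))
            run_start = None
    if run_start is not None:
        out.append(GenomicInterval(chrom, int(run_start),
                                   int(starts[-1] + min_length)))
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_st
# ---------------------------------------------------------------------------

def _wc_components(panel: GenotypePanel, pools: list[list[str]]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    Two-or-more diploid populations, no inbreeding correction; sites where
    any pool has no called genotype yield NaN components.
    """
    r = len(pools)
    ns, ps, hs = [], [], []
    for pool in pools:
        idx = panel.sample_indices(pool)
        g = panel.genotypes[:, idx, :]
        called = (g >= 0).all(axis=2)
        n_i = called.sum(axis=1).astype(float)            # diploid individuals
        alt = ((g == 1) & called[..., None]).sum(axis=(1, 2))
        het = (called & (g[..., 0] != g[..., 1])).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(alt / np.maximum(2 * n_i, 1))
            hs.append(het / np.maximum(n_i, 1))
        ns.append(n_i)
    n = np.stack(ns)          # (r, sites)
    p = np.stack(ps)
    h = np.stack(hs)
    valid = (n > 0).all(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n.mean(axis=0)
        n_c = (r * n_bar - (n ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)
        inner = (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                   - h_bar * (2 * n_bar - 1) / (4 * n_bar))
        c = h_bar / 2
    bad = ~valid | (n_bar <= 1) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_fst(panel: GenotypePanel, pool_a: list[str], pool_b: list[str]
             ) -> np.ndarray:
    """Per-site Weir-Cockerham theta between two sample pools (NaN where
    undefined, including monomorphic sites)."""
    a, b, c = _wc_components(panel, [pool_a, pool_b])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    theta[np.isclose(denom, 0.0)] = np.nan
    return theta


def windowed_fst(panel: GenotypePanel, pool_a: list[str], pool_b: list[str],
                 chrom_lengths: dict[str, int],
                 window_size: int = 1_000_000) -> pd.DataFrame:
    """Windowed (weighted) Weir-Cockerham F_st: ratio of summed components."""
    a, b, c = _wc_components(panel, [pool_a, pool_b])
    windows = make_windows(chrom_lengths, window_size)
    widx = _site_window_index(panel.sites, windows)
    num = np.zeros(len(windows))
    den = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=int)
    sel = (widx >= 0) & np.isfinite(a + b + c)
    np.add.at(num, widx[sel], a[sel])
    np.add.at(den, widx[sel], (a + b + c)[sel])
    np.add.at(counts, widx[sel], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(np.isclose(den, 0.0), np.nan, num / den)
    return _window_frame(windows, values, counts, "fst")


# ---------------------------------------------------------------------------
# ancestry-informative markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AIM:
    chrom: str
    pos: int
    fst: float
    allele_a: int  # diagnostic (major) allele index in the first pool
    allele_b: int


def select_aims(colony_callset: GenotypePanel,
                conserved_callset: GenotypePanel,
                pure_a_colonies: list[str], pure_b_colonies: list[str],
                fst_min: float = 0.8, n_max: int | None = None) -> list[AIM]:
    """Select AIMs between two pooled subspecies.

    Sites need pooled F_st strictly above ``fst_min``, presence in both
    callsets, and distinct major alleles between the pools. When ``n_max``
    is given the top sites by F_st are kept, ties broken by coordinate.
    """
    import warnings

    pool_a = [s for c in pure_a_colonies for s in colony_callset.colony_samples(c)]
    pool_b = [s for c in pure_b_colonies for s in colony_callset.colony_samples(c)]
    theta = site_fst(colony_callset, pool_a, pool_b)
    pa = colony_callset.allele_frequency(pool_a)
    pb = colony_callset.allele_frequency(pool_b)
    major_a = (pa > 0.5).astype(int)
    major_b = (pb > 0.5).astype(int)

    conserved_keys = set(zip(conserved_callset.sites["chrom"],
                             conserved_callset.sites["pos"]))
    aims = []
    for i in np.flatnonzero(np.nan_to_num(theta, nan=-1) > fst_min):
        chrom = colony_callset.sites.at[i, "chrom"]
        pos = int(colony_callset.sites.at[i, "pos"])
        if (chrom, pos) not in conserved_keys:
            continue
        if major_a[i] == major_b[i]:
            continue
        aims.append(AIM(chrom, pos, float(theta[i]),
                        int(major_a[i]), int(major_b[i])))
    aims.sort(key=lambda a: (-a.fst, a.chrom, a.pos))
    if n_max is not None:
        if len(aims) < n_max:
            warnings.warn(f"only {len(aims)} AIMs available (requested {n_max})",
                          stacklevel=2)
        aims = aims[:n_max]
    aims.sort(key=lambda a: (a.chrom, a.pos))
    return aims


def aim_ancestry_fraction(aims: list[AIM], panel: GenotypePanel, colony: str,
                          donor_is_a: bool) -> float:
    """Fraction of AIM loci at which the donor's diagnostic allele predominates.

    "Predominant" means frequency strictly above 0.5 in the colony; AIM loci
    with no called genotype in the colony are excluded from the denominator.
    """
    samples = panel.colony_samples(colony)
    key = {(c, p): i for i, (c, p) in
           enumerate(zip(panel.sites["chrom"], panel.sites["pos"]))}
    freq = panel.allele_frequency(samples)
    n_callable = 0
    n_donor = 0
    for aim in aims:
        i = key.get((aim.chrom, aim.pos))
        if i is None or np.isnan(freq[i]):
            continue
        n_callable += 1
        donor_allele = aim.allele_a if donor_is_a else aim.allele_b
        p_donor = freq[i] if donor_allele == 1 else 1 - freq[i]
        if p_donor > 0.5:
            n_donor += 1
    if n_callable == 0:
        raise ValueError(f"no callable AIMs in colony {colony!r}")
    return n_donor / n_callable


# ---------------------------------------------------------------------------
# founder-haplotype clustering
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    sample: str
    phase: int
    interval: GenomicInterval
    positions: np.ndarray   # 1-based site positions within the interval
    alleles: np.ndarray     # allele indices at those positions

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.alleles):
            raise ValueError("positions and alleles must have equal length")

    @property
    def length(self) -> int:
        return self.interval.length


def cluster_founder_haplotypes(haplotypes: list[Haplotype],
                               max_diff_per_kb: float = 1.0,
                               min_overlap: int = 1_000
                               ) -> tuple[list[int], list[list[Haplotype]]]:
    """Greedy founder clustering of phase blocks, longest first.

    Each haplotype is compared against the representative (longest member) of
    existing clusters; it joins the first whose representative differs by at
    most ``max_diff_per_kb`` SNPs per kb over their overlap (a haplotype is
    *novel* only above that rate). Haplotypes overlapping no representative
    by at least ``min_overlap`` found no cluster and are left unassigned (-1).

    Returns (assignment per input haplotype, clusters).
    """
    order = sorted(range(len(haplotypes)),
                   key=lambda i: (-haplotypes[i].length, haplotypes[i].sample,
                                  haplotypes[i].phase))
    assignment = [-1] * len(haplotypes)
    clusters: list[list[Haplotype]] = []
    reps: list[Haplotype] = []
    for i in order:
        h = haplotypes[i]
        placed = False
        overlapped_any = False
        for ci, rep in enumerate(reps):
            ov = h.interval.intersection_length(rep.interval)
            if ov < min_overlap:
                continue
            overlapped_any = True
            lo = max(h.interval.start, rep.interval.start)
            hi = min(h.interval.end, rep.interval.end)
            in_h = (h.positions - 1 >= lo) & (h.positions - 1 < hi)
            shared = {int(p): int(a) for p, a in
                      zip(rep.positions, rep.alleles)}
            diffs = sum(1 for p, a in zip(h.positions[in_h], h.alleles[in_h])
                        if p in shared and shared[p] != a)
            if diffs / (ov / 1000.0) <= max_diff_per_kb:
                clusters[ci].append(h)
                assignment[i] = ci
                placed = True
                break
        if not placed:
            if reps and not overlapped_any and clusters:
                continue  # unassigned: insufficient overlap with any cluster
            clusters.append([h])
            reps.append(h)
            assignment[i] = len(clusters) - 1
    return assignment, clusters
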