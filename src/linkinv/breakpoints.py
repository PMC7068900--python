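"""Inversion breakpoint validation from long reads and reassembled contigs.

An inversion of the segment ``[s, e)`` creates two novel junctions. For each
candidate call a small *pan-genome* is built containing, for both
breakpoints, the reference-orientation junction sequence and the artificially
inverted junction sequence (optionally plus the rest of the chromosome with
the native breakpoint neighbourhoods masked). Long reads are competitively
aligned against these contigs; a read supports an orientation only if it
spans at least 1 kb on both sides of the junction point on the winning
contig (dual-span rule). Ties between the reference and inverted contig of
one junction are ambiguous and excluded from both the numerator and the
denominator of the inverted fraction.

Decision thresholds follow the published calibration: a breakpoint is
discarded below 10x assigned coverage or above an upper Tukey fence
(Q3 + 2 x IQR) of the null coverage distribution, and passes if more than
37% of assigned reads support the inverted junction. The null is a set of
artificial, repeat-matched, *uninverted* breakpoints used to measure the
typical level of misassignment (the published bound is a false-validation
rate under 1% per breakpoint).

Assembly-based validation classifies alignment segments of reassembled
supercontigs (> 10 kb, per-segment score > 60): a supercontig whose adjacent
segments join the two *upstream* flanks (or the two *downstream* flanks) of
the breakpoint pair with opposite strands carries the signature of an
inverted junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import KmerDiagonalAligner, revcomp

MIN_SPAN_BP = 1_000
MIN_READ_LENGTH = 5_000
DEFAULT_FLANK = 10_000
DEFAULT_MIN_COV = 10
DEFAULT_FENCE = 2.0
DEFAULT_MIN_FRAC = 0.37


@dataclass(frozen=True)
class BreakpointPair:
    """The two junction positions of a candidate inversion ``[bp1, bp2)``."""

    inversion_id: str
    chrom: str
    bp1: int
    bp2: int

    def __post_init__(self) -> None:
        if not self.bp1 < self.bp2:
            raise ValueError(f"{self.inversion_id}: need bp1 < bp2")


@dataclass
class PanGenome:
    """Competitive alignment target for one candidate inversion."""

    call: BreakpointPair
    flank: int
    contigs: dict[str, str]
    #: junction point position within each junction contig
    junction_pos: dict[str, int]
    background: str | None = None

    def alignment_contigs(self) -> dict[str, str]:
        out = dict(self.contigs)
        if self.background is not None:
            out["background"] = self.background
        return out


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    breakpoint: str      # "bp1" | "bp2" | ""
    orientation: str     # "ref" | "inv" | "ambiguous" | "unassigned"
    left_span: int = 0
    right_span: int = 0


@dataclass
class NullCalibration:
    """Coverage and inverted-fraction distributions on uninverted loci."""

    coverages: np.ndarray
    inverted_fractions: np.ndarray  # NaN where a locus had no assigned reads

    def __post_init__(self) -> None:
        self.coverages = np.asarray(self.coverages, dtype=float)
        self.inverted_fractions = np.asarray(self.inverted_fractions, dtype=float)
        if len(self.coverages) == 0:
            raise ValueError("null calibration needs >= 1 artificial breakpoint")
        if not np.any(self.coverages > 0):
            raise ValueError("null calibration failed: all-zero coverage")

    @property
    def n_regions(self) -> int:
        return len(self.coverages)

    def coverage_quartiles(self) -> tuple[float, float, float]:
        """(Q1, Q2, Q3) by linear interpolation (type-7)."""
        q1, q2, q3 = np.quantile(self.coverages, [0.25, 0.5, 0.75])
        return float(q1), float(q2), float(q3)

    @property
    def coverage_iqr(self) -> float:
        q1, _, q3 = self.coverage_quartiles()
        return q3 - q1

    def coverage_fences(self, fence: float = DEFAULT_FENCE) -> tuple[float, float]:
        q1, _, q3 = self.coverage_quartiles()
        iqr = q3 - q1
        return q1 - fence * iqr, q3 + fence * iqr

    def misassignment_rate(self, threshold: float = DEFAULT_MIN_FRAC) -> float:
        """Fraction of null breakpoints whose inverted fraction exceeds ``threshold``."""
        frac = np.nan_to_num(self.inverted_fractions, nan=0.0)
        return float(np.mean(frac > threshold))

    def false_validation_rate(self, min_cov: int = DEFAULT_MIN_COV,
                              fence: float = DEFAULT_FENCE,
                              min_frac: float = DEFAULT_MIN_FRAC,
                              both_tails: bool = False) -> float:
        """Fraction of null breakpoints passing the *full* per-breakpoint rule."""
        lo, hi = self.coverage_fences(fence)
        cov_ok = (self.coverages >= min_cov) & (self.coverages <= hi)
        if both_tails:
            cov_ok &= self.coverages >= lo
        frac = np.nan_to_num(self.inverted_fractions, nan=0.0)
        return float(np.mean(cov_ok & (frac > min_frac)))


@dataclass
class BreakpointDecision:
    coverage: int
    n_inv: int
    n_ref: int
    inverted_fraction: float
    coverage_pass: bool
    fraction_pass: bool
    reason: str = ""

    @property
    def passes(self) -> bool:
        return self.coverage_pass and self.fraction_pass


@dataclass
class ValidationResult:
    inversion_id: str
    breakpoints: dict[str, BreakpointDecision] = field(default_factory=dict)
    method: str = "long_read"  # "long_read" | "assembly" | "both"

    @property
    def overall_valid(self) -> bool:
        return (len(self.breakpoints) == 2
                and all(b.passes for b in self.breakpoints.values()))


# ---------------------------------------------------------------------------
# pan-genome construction
# ---------------------------------------------------------------------------

def build_pangenome(reference: str, call: BreakpointPair,
                    flank: int = DEFAULT_FLANK,
                    include_background: bool = False) -> PanGenome:
    """Build the four junction contigs (and optionally the masked background).

    For the inversion of ``[s, e)`` with flank ``F``::

        bp1_ref = seq[s-F : s+F]
        bp2_ref = seq[e-F : e+F]
        bp1_inv = seq[s-F : s] ++ revcomp(seq[e-F : e])
        bp2_inv = revcomp(seq[s : s+F]) ++ seq[e : e+F]

    Flanks are truncated (with a warning) at chromosome ends; the junction
    point of each contig is recorded so span rules survive truncation.
    """
    if flank < MIN_SPAN_BP:
        raise ValueError(f"flank {flank} < minimum span {MIN_SPAN_BP}")
    s, e = call.bp1, call.bp2
    if e - s < flank:
        warnings.warn(
            f"{call.inversion_id}: inversion ({e - s} bp) shorter than flank "
            f"({flank} bp); inner flanks overlap", stacklevel=2)
    lf1 = min(flank, s)                      # left flank available at bp1
    rf2 = min(flank, len(reference) - e)     # right flank available at bp2
    if lf1 < flank or rf2 < flank:
        warnings.warn(f"{call.inversion_id}: flank truncated at chromosome end",
                      stacklevel=2)
    contigs = {
        "bp1_ref": reference[s - lf1:s + flank],
        "bp2_ref": reference[e - flank:e + rf2],
        "bp1_inv": reference[s - lf1:s] + revcomp(reference[e - flank:e]),
        "bp2_inv": revcomp(reference[s:s + flank]) + reference[e:e + rf2],
    }
    junction_pos = {"bp1_ref": lf1, "bp1_inv": lf1,
                    "bp2_ref": flank, "bp2_inv": flank}
    background = None
    if include_background:
        bg = np.frombuffer(reference.encode(), dtype=np.uint8).copy()
        bg[max(0, s - flank):s + flank] = ord("N")
        bg[max(0, e - flank):e + rf2] = ord("N")
        background = bg.tobytes().decode()
    return PanGenome(call=call, flank=flank, contigs=contigs,
                     junction_pos=junction_pos, background=background)


# ---------------------------------------------------------------------------
# competitive read assignment
# ---------------------------------------------------------------------------

def assign_reads(reads: list[tuple[str, str]], pangenome: PanGenome,
                 aligner=None, min_read_length: int = MIN_READ_LENGTH,
                 min_span: int = MIN_SPAN_BP) -> list[ReadAssignment]:
    """Competitively assign long reads to junction contigs.

    Reads of length <= ``min_read_length`` are skipped (the longest-read
    selection rule). Each remaining read goes to the contig with the best
    alignment score; orientation (ref/inv) is recorded only when the read
    spans ``min_span`` on both sides of the junction point on the winning
    contig. Equal best scores on the ref and inv contig of the same junction
    yield ``ambiguous``; best alignment on the masked background (or no
    alignment at all) yields ``unassigned``.
    """
    if aligner is None:
        aligner = KmerDiagonalAligner(pangenome.alignment_contigs(),
                                      split_points=pangenome.junction_pos)
    out = []
    for read_id, seq in reads:
        if len(seq) <= min_read_length:
            continue
        try:
            hits = aligner.best_hits(seq)
        except Exception:
            out.append(ReadAssignment(read_id, "", "unassigned"))
            continue
        if not hits:
            out.append(ReadAssignment(read_id, "", "unassigned"))
            continue
        best = hits[0]
        if best.contig == "background":
            out.append(ReadAssignment(read_id, "", "unassigned"))
            continue
        bp, orient = best.contig.split("_")
        jpos = pangenome.junction_pos[best.contig]
        left = jpos - best.contig_start
        right = best.contig_end - jpos
        if left < min_span or right < min_span:
            # dual-span rule first: flank-only reads are uninformative
            out.append(ReadAssignment(read_id, bp, "unassigned", left, right))
            continue
        # tie with the opposite-orientation contig of the same junction?
        other = f"{bp}_{'ref' if orient == 'inv' else 'inv'}"
        other_score = max((h.score for h in hits if h.contig == other),
                          default=-np.inf)
        if other_score == best.score:
            out.append(ReadAssignment(read_id, bp, "ambiguous", left, right))
        else:
            out.append(ReadAssignment(read_id, bp, orient, left, right))
    return out


def breakpoint_counts(assignments: list[ReadAssignment], breakpoint: str
                      ) -> tuple[int, int]:
    """(n_inv, n_ref) dual-span assignments for one junction."""
    n_inv = sum(1 for a in assignments
                if a.breakpoint == breakpoint and a.orientation == "inv")
    n_ref = sum(1 for a in assignments
                if a.breakpoint == breakpoint and a.orientation == "ref")
    return n_inv, n_ref


# ---------------------------------------------------------------------------
# repeat-matched artificial breakpoints (the null)
# ---------------------------------------------------------------------------

def _repeat_cumsum(length: int, repeats) -> np.ndarray:
    mask = np.zeros(length, dtype=np.uint8)
    for r in repeats.itertuples():
        mask[max(0, int(r.start)):min(length, int(r.end))] = 1
    return np.concatenate([[0], np.cumsum(mask, dtype=np.int64)])


def _flank_repeat_fraction(cs: np.ndarray, pos: int, flank: int) -> float:
    lo, hi = max(0, pos - flank), min(len(cs) - 1, pos + flank)
    if hi <= lo:
        return 0.0
    return float(cs[hi] - cs[lo]) / (hi - lo)


def candidate_repeat_fractions(reference: dict[str, str], repeats,
                               candidates: list[BreakpointPair],
                               flank: int = DEFAULT_FLANK) -> np.ndarray:
    """Mean flank repeat fraction of each candidate's two junctions."""
    cums = {c: _repeat_cumsum(len(reference[c]),
                              repeats[repeats["chrom"] == c])
            for c in reference}
    out = []
    for cand in candidates:
        cs = cums[cand.chrom]
        out.append(0.5 * (_flank_repeat_fraction(cs, cand.bp1, flank)
                          + _flank_repeat_fraction(cs, cand.bp2, flank)))
    return np.array(out)


def generate_artificial_breakpoints(reference: dict[str, str], repeats,
                                    candidates: list[BreakpointPair],
                                    n: int = 1000, seed: int = 0,
                                    flank: int = DEFAULT_FLANK,
                                    tolerance: float = 0.10,
                                    max_attempts: int = 200
                                    ) -> list[BreakpointPair]:
    """Sample ``n`` uninverted breakpoint pairs repeat-matched to the candidates.

    Each artificial locus targets the flank repeat fraction of a candidate
    (sampled with replacement) and is accepted when its own flank repeat
    fraction lies within ``tolerance`` (fraction points) of the target;
    after ``max_attempts`` rejections the tolerance for that locus is doubled
    with a warning. Sizes are drawn from the candidate size distribution with
    mild log jitter. Deterministic under ``seed``.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    chroms = list(reference)
    cums = {c: _repeat_cumsum(len(reference[c]),
                              repeats[repeats["chrom"] == c]) for c in chroms}
    targets = candidate_repeat_fractions(reference, repeats, candidates, flank)
    sizes = np.array([c.bp2 - c.bp1 for c in candidates], dtype=float)
    out = []
    for i in range(n):
        pick = int(rng.integers(len(candidates)))
        target = targets[pick]
        size = int(sizes[pick] * rng.uniform(0.8, 1.25))
        tol = tolerance
        for attempt in range(max_attempts * 2):
            if attempt == max_attempts:
                tol *= 2
                warnings.warn("artificial-breakpoint matching relaxed "
                              f"(locus {i}, tolerance {tol:.2f})", stacklevel=2)
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = len(reference[chrom])
            if length < size + 2 * flank + 2:
                continue
            s = int(rng.integers(flank, length - size - flank))
            e = s + size
            cs = cums[chrom]
            frac = 0.5 * (_flank_repeat_fraction(cs, s, flank)
                          + _flank_repeat_fraction(cs, e, flank))
            if abs(frac - target) <= tol:
                out.append(BreakpointPair(f"null{i}", chrom, s, e))
                break
        else:  # pragma: no cover - pathological configs only
            raise RuntimeError("could not repeat-match artificial breakpoints")
    return out


def calibrate_null(null_assignments: list[list[ReadAssignment]]
                   ) -> NullCalibration:
    """Summarise per-junction coverage and inverted fraction over the null set.

    ``null_assignments`` holds one assignment list per artificial breakpoint
    pair; both junctions of each pair contribute one observation.
    """
    covs, fracs = [], []
    for assignments in null_assignments:
        for bp in ("bp1", "bp2"):
            n_inv, n_ref = breakpoint_counts(assignments, bp)
            cov = n_inv + n_ref
            covs.append(cov)
            fracs.append(n_inv / cov if cov > 0 else np.nan)
    return NullCalibration(np.array(covs, dtype=float),
                           np.array(fracs, dtype=float))


# ---------------------------------------------------------------------------
# the per-inversion decision
# ---------------------------------------------------------------------------

def validate_inversion(assignments: list[ReadAssignment],
                       null: NullCalibration,
                       inversion_id: str = "",
                       min_cov: int = DEFAULT_MIN_COV,
                       fence: float = DEFAULT_FENCE,
                       min_frac: float = DEFAULT_MIN_FRAC,
                       both_tails: bool = False) -> ValidationResult:
    """Apply the calibrated per-breakpoint rule; valid iff both junctions pass."""
    lo, hi = null.coverage_fences(fence)
    result = ValidationResult(inversion_id=inversion_id)
    for bp in ("bp1", "bp2"):
        n_inv, n_ref = breakpoint_counts(assignments, bp)
        cov = n_inv + n_ref
        frac = n_inv / cov if cov > 0 else 0.0
        reason = ""
        cov_ok = True
        if cov == 0:
            cov_ok, reason = False, "no coverage"
        elif cov < min_cov:
            cov_ok, reason = False, f"coverage {cov} < {min_cov}"
        elif cov > hi or (both_tails and cov < lo):
            cov_ok, reason = False, f"coverage {cov} outside null fence"
        frac_ok = frac > min_frac
        if cov_ok and not frac_ok:
            reason = f"inverted fraction {frac:.3f} <= {min_frac}"
        result.breakpoints[bp] = BreakpointDecision(
            coverage=cov, n_inv=n_inv, n_ref=n_ref, inverted_fraction=frac,
            coverage_pass=cov_ok, fraction_pass=frac_ok, reason=reason)
    return result


# ---------------------------------------------------------------------------
# supercontig (assembly) classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SupercontigSegment:
    """One alignment segment of a reassembled supercontig, in contig order."""

    target_start: int
    target_end: int
    strand: int      # +1 / -1
    score: float


def _flank_label(seg: SupercontigSegment, call: BreakpointPair, flank: int
                 ) -> str | None:
    mid = (seg.target_start + seg.target_end) // 2
    for bp, pos in (("bp1", call.bp1), ("bp2", call.bp2)):
        if pos - flank <= mid < pos:
            return f"{bp}_up"
        if pos <= mid < pos + flank:
            return f"{bp}_down"
    return None


def classify_supercontig(segments: list[SupercontigSegment],
                         call: BreakpointPair,
                         supercontig_length: int,
                         flank: int = 50_000,
                         min_length: int = 10_000,
                         min_score: float = 60.0) -> dict:
    """Classify one supercontig's junction signature.

    Adjacent segments joining the two *upstream* flanks of bp1/bp2 with
    opposite strands support the bp1 inverted junction; the two *downstream*
    flanks with opposite strands support bp2. Colinear same-side joins are
    the reference configuration. Supercontigs of <= ``min_length`` or with no
    segment scoring above ``min_score`` give no support (not an error).
    """
    support = {"bp1": False, "bp2": False}
    if supercontig_length <= min_length:
        return {**support, "supports_inversion": False}
    kept = [s for s in segments if s.score > min_score]
    labels = [_flank_label(s, call, flank) for s in kept]
    for (a, la), (b, lb) in zip(zip(kept, labels), zip(kept[1:], labels[1:])):
        if la is None or lb is None or a.strand == b.strand:
            continue
        sides = {la, lb}
        if sides == {"bp1_up", "bp2_up"}:
            support["bp1"] = True
        elif sides == {"bp1_down", "bp2_down"}:
            support["bp2"] = True
    return {**support, "supports_inversion": support["bp1"] or support["bp2"]}


def assembly_validation(supercontigs: list[tuple[list[SupercontigSegment], int]],
                        call: BreakpointPair, **kwargs) -> bool:
    """Assembly-validated iff both junctions are supported across supercontigs."""
    seen = {"bp1": False, "bp2": False}
    for segments, length in supercontigs:
        res = classify_supercontig(segments, call, length, **kwargs)
        seen["bp1"] |= res["bp1"]
        seen["bp2"] |= res["bp2"]
    return seen["bp1"] and seen["bp2"]
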