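"""Long-read alignment interface for competitive junction assignment.

Two implementations are provided behind the same duck-typed surface
(``best_hits(read) -> list[AlignmentHit]``):

``KmerDiagonalAligner``
    A built-in seed-and-vote aligner. Contigs are indexed with exact k-mers;
    a read's k-mers vote for diagonals and the winning diagonal is scored by
    ungapped base comparison. This is sufficient (and fast) for reads whose
    errors are substitutions, which is what the read simulator produces, and
    it is fully deterministic.

``Minimap2Aligner``
    A thin subprocess adapter around the ``minimap2`` executable emitting
    PAF records, for externally supplied reads with indels.

Scores are normalised to matches minus ``mismatch_penalty`` x mismatches so
that competitive comparisons between contigs are on one scale.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_CODE = np.full(256, 4, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

_COMP_BYTES = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP_BYTES[_a] = _b


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP_BYTES[arr[::-1]].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integers and a validity mask (k-mers containing N are invalid)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        invalid |= c == 4
        vals = vals * 4 + np.where(c == 4, 0, c)
    return vals, ~invalid


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped (or projected) alignment of a read against one contig."""

    contig: str
    strand: int            # +1 read as-is, -1 reverse complement
    score: float           # matches - penalty * mismatches
    matches: int
    contig_start: int      # 0-based on the contig
    contig_end: int


class KmerDiagonalAligner:
    """Seed-and-vote ungapped aligner over a fixed contig set.

    A contig may declare a *split point* (``split_points``): alignments are
    then scored as two segments — one per side of the split — each on its own
    best diagonal. Junction contigs built from imprecise breakpoint
    coordinates shift the two sides of a spanning read by a few tens of
    bases relative to each other; the split scoring absorbs that offset the
    way a gapped aligner would.
    """

    def __init__(self, contigs: dict[str, str], k: int = 15,
                 read_stride: int = 12, min_votes: int = 3,
                 mismatch_penalty: float = 2.0,
                 split_points: dict[str, int] | None = None,
                 max_split_shift: int = 500) -> None:
        self.k = k
        self.read_stride = read_stride
        self.min_votes = min_votes
        self.mismatch_penalty = mismatch_penalty
        self._splits = dict(split_points or {})
        self.max_split_shift = max_split_shift
        self._codes: dict[str, np.ndarray] = {}
        self._index: dict[str, dict[int, np.ndarray]] = {}
        for name, seq in contigs.items():
            codes = _encode(seq)
            self._codes[name] = codes
            vals, ok = _kmer_values(codes, k)
            pos = np.flatnonzero(ok)
            v = vals[pos]
            order = np.argsort(v, kind="stable")
            v_sorted, pos_sorted = v[order], pos[order]
            starts = np.flatnonzero(np.r_[True, v_sorted[1:] != v_sorted[:-1]])
            table: dict[int, np.ndarray] = {}
            bounds = np.r_[starts, len(v_sorted)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                table[int(v_sorted[a])] = pos_sorted[a:b]
            self._index[name] = table

    def _read_seeds(self, rcodes: np.ndarray) -> list[tuple[int, int]]:
        vals, ok = _kmer_values(rcodes, self.k)
        return [(rp, int(vals[rp]))
                for rp in range(0, len(vals), self.read_stride) if ok[rp]]

    @staticmethod
    def _best_diagonal(chunks: list[np.ndarray], min_votes: int) -> int | None:
        if not chunks:
            return None
        diags, counts = np.unique(np.concatenate(chunks), return_counts=True)
        top = counts.max()
        if top < min_votes:
            return None
        tied = diags[counts == top]
        return int(tied[np.argmin(np.abs(tied))])

    def _segment(self, rcodes: np.ndarray, contig: np.ndarray, diag: int,
                 lo: int, hi: int) -> tuple[int, int, int, int] | None:
        """Score the read against contig[lo:hi) on one diagonal.

        Returns (matches, mismatches, contig_start, contig_end).
        """
        r0 = max(0, lo - diag)
        r1 = min(len(rcodes), hi - diag, len(contig) - diag)
        r0 = max(r0, -diag)
        if r1 <= r0:
            return None
        a = rcodes[r0:r1]
        b = contig[r0 + diag:r1 + diag]
        comparable = (a != 4) & (b != 4)
        matches = int(np.sum((a == b) & comparable))
        mismatches = int(np.sum(comparable)) - matches
        return matches, mismatches, r0 + diag, r1 + diag

    def _hit_one(self, rcodes: np.ndarray, seeds: list[tuple[int, int]],
                 name: str, strand: int) -> AlignmentHit | None:
        table = self._index[name]
        get = table.get
        split = self._splits.get(name)
        left_chunks: list[np.ndarray] = []
        right_chunks: list[np.ndarray] = []
        for rp, v in seeds:
            hits = get(v)
            if hits is None or len(hits) > 50:  # skip hyper-repetitive seeds
                continue
            if split is None:
                left_chunks.append(hits - rp)
            else:
                left = hits[hits < split]
                right = hits[hits >= split]
                if len(left):
                    left_chunks.append(left - rp)
                if len(right):
                    right_chunks.append(right - rp)
        contig = self._codes[name]
        if split is None:
            diag = self._best_diagonal(left_chunks, self.min_votes)
            if diag is None:
                return None
            segments = [(diag, 0, len(contig))]
        else:
            d_left = self._best_diagonal(left_chunks, self.min_votes)
            d_right = self._best_diagonal(right_chunks, self.min_votes)
            if d_left is not None and d_right is not None \
                    and abs(d_left - d_right) > self.max_split_shift:
                # discordant sides: keep the better-supported one
                votes = {d_left: sum(np.sum(c == d_left) for c in left_chunks),
                         d_right: sum(np.sum(c == d_right)
                                      for c in right_chunks)}
                if votes[d_left] >= votes[d_right]:
                    d_right = None
                else:
                    d_left = None
            segments = [(d, lo, hi) for d, lo, hi in
                        ((d_left, 0, split), (d_right, split, len(contig)))
                        if d is not None]
            if not segments:
                return None
        matches = mismatches = 0
        c_start, c_end = len(contig), 0
        for diag, lo, hi in segments:
            seg = self._segment(rcodes, contig, diag, lo, hi)
            if seg is None:
                continue
            m, mm, s, e = seg
            matches += m
            mismatches += mm
            c_start = min(c_start, s)
            c_end = max(c_end, e)
        if c_end <= c_start:
            return None
        score = matches - self.mismatch_penalty * mismatches
        return AlignmentHit(contig=name, strand=strand, score=score,
                            matches=matches, contig_start=c_start,
                            contig_end=c_end)

    def best_hits(self, read: str) -> list[AlignmentHit]:
        """Best hit per (contig, strand), sorted by descending score."""
        fwd = _encode(read)
        rev = fwd[::-1].copy()
        rev[rev < 4] = 3 - rev[rev < 4]
        hits = []
        for rcodes, strand in ((fwd, 1), (rev, -1)):
            seeds = self._read_seeds(rcodes)
            if not seeds:
                continue
            for name in self._codes:
                h = self._hit_one(rcodes, seeds, name, strand)
                if h is not None:
                    hits.append(h)
        hits.sort(key=lambda h: (-h.score, h.contig, h.strand))
        return hits


class Minimap2Aligner:
    """Adapter running the external ``minimap2`` binary (PAF output).

    Scores are the PAF residue-match count minus ``mismatch_penalty`` times
    the remaining alignment-block length, mirroring the built-in scale.
    """

    def __init__(self, contigs: dict[str, str], preset: str = "map-ont",
                 mismatch_penalty: float = 2.0) -> None:
        if shutil.which("minimap2") is None:
            raise RuntimeError("minimap2 executable not found on PATH")
        self.contigs = contigs
        self.preset = preset
        self.mismatch_penalty = mismatch_penalty

    def best_hits(self, read: str) -> list[AlignmentHit]:
        with tempfile.TemporaryDirectory() as tmp:
            ref = Path(tmp, "ref.fa")
            qry = Path(tmp, "read.fa")
            ref.write_text("".join(f">{n}\n{s}\n" for n, s in self.contigs.items()))
            qry.write_text(f">read\n{read}\n")
            out = subprocess.run(
                ["minimap2", "-x", self.preset, "--secondary=yes", "-N", "10",
                 str(ref), str(qry)],
                capture_output=True, text=True, check=True).stdout
        best: dict[tuple[str, int], AlignmentHit] = {}
        for line in out.splitlines():
            f = line.split("\t")
            strand = 1 if f[4] == "+" else -1
            matches = int(f[9])
            block = int(f[10])
            score = matches - self.mismatch_penalty * (block - matches)
            hit = AlignmentHit(contig=f[5], strand=strand, score=score,
                               matches=matches, contig_start=int(f[7]),
                               contig_end=int(f[8]))
            key = (hit.contig, strand)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
        return sorted(best.values(), key=lambda h: (-h.score, h.contig, h.strand))
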