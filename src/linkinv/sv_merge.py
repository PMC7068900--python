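"""Merging of per-sample, per-caller inversion candidates into loci.

Candidates from independent samples and callers are clustered by
single-linkage under a reciprocal-overlap criterion (default 0.95) and each
merged call records its caller and sample support, size class (micro = under
500 kb, strict), and the span of its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, reciprocal_overlap

MICRO_MAX_BP = 500_000  #: strict upper bound for a microinversion


@dataclass(frozen=True)
class InversionCandidate:
    interval: GenomicInterval
    sample: str
    caller: str
    quality: float | None = None

    def __post_init__(self) -> None:
        if not self.caller:
            raise ValueError("caller label must be non-empty")


@dataclass
class InversionCall:
    """A merged inversion locus with support provenance."""

    id: str
    interval: GenomicInterval
    members: list[InversionCandidate]
    callers: set[str] = field(default_factory=set)
    samples: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return self.interval.length

    @property
    def is_micro(self) -> bool:
        return self.size < MICRO_MAX_BP

    def breakpoints(self) -> tuple[int, int]:
        """Representative breakpoints: median of member endpoints."""
        starts = sorted(m.interval.start for m in self.members)
        ends = sorted(m.interval.end for m in self.members)
        return (int(np.median(starts)), int(np.median(ends)))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_candidates(candidates: list[InversionCandidate],
                     threshold: float = 0.95,
                     arm_of: dict[str, list[tuple[int, str]]] | None = None
                     ) -> list[InversionCall]:
    """Single-linkage clustering of candidates at reciprocal overlap >= threshold.

    Clustering runs across samples and callers; the merged interval is the
    union span of the members. Output is deterministically ordered by
    (chrom, start) and invariant to the input order of ``candidates``.

    Parameters
    ----------
    arm_of : optional
        Chromosome-arm boundaries for call naming, ``{chrom: [(start, "p"),
        (start, "q"), ...]}``; without it calls are named ``<chrom><letters>``.
    """
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i].interval.chrom,
                                  candidates[i].interval.start,
                                  candidates[i].interval.end,
                                  candidates[i].sample, candidates[i].caller))
    cand = [candidates[i] for i in order]
    uf = _UnionFind(len(cand))
    # sweep within chromosome: only pairs whose spans overlap can merge
    active: list[int] = []
    for i, c in enumerate(cand):
        active = [j for j in active
                  if cand[j].interval.chrom == c.interval.chrom
                  and cand[j].interval.end > c.interval.start]
        for j in active:
            if reciprocal_overlap(c.interval, cand[j].interval) >= threshold:
                uf.union(i, j)
        active.append(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(cand)):
        groups.setdefault(uf.find(i), []).append(i)

    calls = []
    for members_idx in groups.values():
        members = [cand[i] for i in members_idx]
        chrom = members[0].interval.chrom
        interval = GenomicInterval(chrom,
                                   min(m.interval.start for m in members),
                                   max(m.interval.end for m in members))
        calls.append(InversionCall(
            id="", interval=interval, members=members,
            callers={m.caller for m in members},
            samples={m.sample for m in members}))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    _assign_names(calls, arm_of)
    return calls


def _assign_names(calls: list[InversionCall],
                  arm_of: dict[str, list[tuple[int, str]]] | None) -> None:
    """Name calls ``<chrom><arm><letters>`` in coordinate order per arm."""

    def letters(n: int) -> str:
        s = ""
        n += 1
        while n:
            n, r = divmod(n - 1, 26)
            s = chr(ord("a") + r) + s
        return s

    counters: dict[tuple[str, str], int] = {}
    for call in calls:
        arm = ""
        if arm_of and call.interval.chrom in arm_of:
            for boundary, label in arm_of[call.interval.chrom]:
                if call.interval.start >= boundary:
                    arm = label
        key = (call.interval.chrom, arm)
        n = counters.get(key, 0)
        counters[key] = n + 1
        call.id = f"{call.interval.chrom}{arm}{letters(n)}"


def classify_and_count(calls: list[InversionCall]) -> dict:
    """Summary counts over merged calls.

    Returns total, micro (< 500 kb strict) and large counts, the number of
    single-sample calls, per-caller counts (a call with >= 2 callers counts
    under "Both"), and the concordant (>= 2 callers) count.
    """
    per_caller: dict[str, int] = {}
    for c in calls:
        label = "Both" if len(c.callers) >= 2 else next(iter(c.callers))
        per_caller[label] = per_caller.get(label, 0) + 1
    return {
        "n_total": len(calls),
        "n_micro": sum(c.is_micro for c in calls),
        "n_large": sum(not c.is_micro for c in calls),
        "n_singleton_sample": sum(len(c.samples) == 1 for c in calls),
        "per_caller": per_caller,
        "concordant": sum(len(c.callers) >= 2 for c in calls),
    }


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_candidates(path: str) -> list[InversionCandidate]:
    """Read a candidate TSV with columns chrom, start, end, sample, caller."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [InversionCandidate(GenomicInterval(r.chrom, int(r.start), int(r.end)),
                               sample=str(r.sample), caller=str(r.caller))
            for r in df.itertuples()]


def candidates_to_frame(candidates: list[InversionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.interval.chrom, c.interval.start, c.interval.end, c.sample, c.caller)
         for c in candidates],
        columns=["chrom", "start", "end", "sample", "caller"])


def calls_to_frame(calls: list[InversionCall]) -> pd.DataFrame:
    """Merged-call table mirroring the published catalog columns."""
    rows = []
    for c in calls:
        rows.append({
            "inversion": c.id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "size": c.size,
            "micro": int(c.is_micro),
            "caller": ("Both" if len(c.callers) >= 2 else next(iter(c.callers))),
            "n_samples": len(c.samples),
            "samples": ",".join(sorted(c.samples)),
        })
    return pd.DataFrame(rows)


def write_calls(calls: list[InversionCall], path: str) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
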