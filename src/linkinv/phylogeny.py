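"""Maximum-parsimony trees from biallelic SNP data.

Characters are binary (0/1, missing = fully ambiguous); tree length is the
Fitch count of minimum state changes, which is invariant to rooting. An
unrooted binary topology over taxa ``0..n-1`` is stored as a rooted nested
tuple over taxa ``1..n-1`` with taxon 0 attached at the root edge — the
classic bijection between unrooted n-leaf trees and rooted (n-1)-leaf trees.

Search is exhaustive for up to 9 taxa (all unrooted topologies) and
stepwise-addition followed by iterated leaf re-insertion hill climbing above
that, reproducible under a seed. Branch support is the bootstrap percentage
of site-resampled replicates whose optimal trees contain the bipartition.
Consensus and Newick serialisation go through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np

EXHAUSTIVE_MAX_TAXA = 9

Topo = int | tuple  # nested tuple over taxon indices 1..n-1


@dataclass
class SnpAlignment:
    """Binary character matrix; rows are taxa, -1 marks missing data."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites) int8 in {0, 1, -1}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix must be (n_taxa, n_sites)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def state_masks(self) -> np.ndarray:
        """Fitch state sets: 0 -> {0}, 1 -> {1}, missing -> {0,1} (bitmasks)."""
        m = self.matrix
        return np.where(m == 0, 1, np.where(m == 1, 2, 3)).astype(np.uint8)


@dataclass
class Tree:
    """An unrooted tree with optional bootstrap supports.

    ``supports`` maps a bipartition — the frozen set of taxon labels on the
    side not containing the first taxon — to a percentage in [0, 100].
    """

    topo: Topo
    taxa: list[str]
    score: float | None = None
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as label sets.

        Each bipartition is keyed by the side *not* containing the
        lexicographically smallest taxon label, so keys are invariant to
        taxon input order.
        """
        out: set[frozenset] = set()
        anchor = min(self.taxa)
        everything = frozenset(self.taxa)

        def walk(t: Topo) -> set[int]:
            if isinstance(t, int):
                return {t}
            leaves = walk(t[0]) | walk(t[1])
            if 1 < len(leaves) < len(self.taxa) - 1:
                side = frozenset(self.taxa[i] for i in leaves)
                out.add(everything - side if anchor in side else side)
            return leaves

        if isinstance(self.topo, tuple):
            walk(self.topo)
        return out

    def clade_sides(self) -> list[set[str]]:
        """One leaf-label side per edge (the side not containing taxon 0)."""
        sides: list[set[str]] = []

        def walk(t: Topo) -> set[int]:
            if isinstance(t, int):
                sides.append({self.taxa[t]})
                return {t}
            leaves = walk(t[0]) | walk(t[1])
            sides.append({self.taxa[i] for i in leaves})
            return leaves

        walk(self.topo)
        return sides

    def newick(self, include_support: bool = False) -> str:
        anchor = min(self.taxa)
        everything = frozenset(self.taxa)

        def fmt(t: Topo) -> str:
            if isinstance(t, int):
                return self.taxa[t]
            inner = f"({fmt(t[0])},{fmt(t[1])})"
            if include_support:
                side = frozenset(self.taxa[i] for i in _leafset(t))
                if anchor in side:
                    side = everything - side
                if side in self.supports:
                    inner += f"{self.supports[side]:.0f}"
            return inner

        return f"({self.taxa[0]},{fmt(self.topo)});"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick(), schema="newick",
                                 taxon_namespace=taxon_namespace)


def _leafset(t: Topo) -> set[int]:
    if isinstance(t, int):
        return {t}
    return _leafset(t[0]) | _leafset(t[1])


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _fitch_masks(topo: Topo, masks: np.ndarray, weights: np.ndarray | None
                 ) -> tuple[np.ndarray, float]:
    def walk(t: Topo) -> tuple[np.ndarray, float]:
        if isinstance(t, int):
            return masks[t], 0.0
        ml, cl = walk(t[0])
        mr, cr = walk(t[1])
        inter = ml & mr
        union_needed = inter == 0
        merged = np.where(union_needed, ml | mr, inter)
        if weights is None:
            add = float(np.count_nonzero(union_needed))
        else:
            add = float(weights[union_needed].sum())
        return merged, cl + cr + add

    return walk(topo)


def fitch_score(tree: Tree | Topo, aln: SnpAlignment,
                weights: np.ndarray | None = None) -> float:
    """Parsimony length of a topology: summed minimum state changes.

    Missing characters carry the full state set and never force a change.
    ``weights`` are per-site multiplicities (used by the bootstrap).
    """
    topo = tree.topo if isinstance(tree, Tree) else tree
    masks = aln.state_masks()
    # root on the edge to taxon 0: score((topo, 0)) — rooting-invariant
    _, score = _fitch_masks((topo, 0), masks, weights)
    return score


# ---------------------------------------------------------------------------
# topology enumeration and editing
# ---------------------------------------------------------------------------

def _insertions(t: Topo, x: int) -> Iterator[Topo]:
    """All topologies obtained by attaching leaf ``x`` on each edge of ``t``."""
    yield (t, x)
    if isinstance(t, tuple):
        for v in _insertions(t[0], x):
            yield (v, t[1])
        for v in _insertions(t[1], x):
            yield (t[0], v)


def enumerate_topologies(n_taxa: int) -> Iterator[Topo]:
    """All unrooted topologies over ``n_taxa`` labelled leaves."""
    if n_taxa < 4:
        raise ValueError("tree search needs >= 4 taxa")

    def build(taxa: list[int]) -> Iterator[Topo]:
        if len(taxa) == 1:
            yield taxa[0]
            return
        for sub in build(taxa[:-1]):
            yield from _insertions(sub, taxa[-1])

    yield from build(list(range(1, n_taxa)))


def _canonical(t: Topo) -> tuple:
    """Order-normalised, totally-orderable form: leaf -> (0, i),
    internal -> (1, a, b) with a <= b."""
    if isinstance(t, int):
        return (0, t)
    a, b = _canonical(t[0]), _canonical(t[1])
    return (1, a, b) if a <= b else (1, b, a)


def _remove_leaf(t: Topo, x: int) -> Topo | None:
    """Remove leaf ``x``, splicing out its parent; None if t collapses to x."""
    if isinstance(t, int):
        return None if t == x else t
    left = _remove_leaf(t[0], x)
    right = _remove_leaf(t[1], x)
    if left is None:
        return right
    if right is None:
        return left
    return (left, right)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def search_mp(aln: SnpAlignment, seed: int = 0,
              n_restarts: int = 3, weights: np.ndarray | None = None,
              max_cooptimal: int = 64) -> list[Tree]:
    """Find minimum-length topologies.

    Exhaustive for <= 9 taxa; otherwise stepwise addition (taxon order
    shuffled per restart under ``seed``) followed by iterated single-leaf
    re-insertion hill climbing. Returns all co-optimal topologies found
    (up to ``max_cooptimal``), deterministically ordered.
    """
    n = aln.n_taxa
    if n < 4:
        raise ValueError("tree search needs >= 4 taxa")
    if n <= EXHAUSTIVE_MAX_TAXA:
        best: dict[tuple, Topo] = {}
        best_score = np.inf
        for topo in enumerate_topologies(n):
            s = fitch_score(topo, aln, weights)
            if s < best_score - 1e-12:
                best_score, best = s, {_canonical(topo): topo}
            elif abs(s - best_score) <= 1e-12 and len(best) < max_cooptimal:
                best.setdefault(_canonical(topo), topo)
        topos = [best[k] for k in sorted(best)]
        return [Tree(t, list(aln.taxa), best_score) for t in topos]

    rng = np.random.default_rng(seed)
    best_score = np.inf
    best: dict[tuple, Topo] = {}
    for _ in range(n_restarts):
        order = [int(x) for x in rng.permutation(np.arange(1, n))]
        topo: Topo = order[0]
        for x in order[1:]:
            cands = list(_insertions(topo, int(x)))
            scores = [fitch_score(c, aln, weights) for c in cands]
            topo = cands[int(np.argmin(scores))]
        score = fitch_score(topo, aln, weights)
        improved = True
        while improved:
            improved = False
            for x in range(1, n):
                pruned = _remove_leaf(topo, x)
                if pruned is None or isinstance(pruned, int):
                    continue
                cands = list(_insertions(pruned, x))
                scores = [fitch_score(c, aln, weights) for c in cands]
                k = int(np.argmin(scores))
                if scores[k] < score - 1e-12:
                    topo, score = cands[k], scores[k]
                    improved = True
        if score < best_score - 1e-12:
            best_score, best = score, {_canonical(topo): topo}
        elif abs(score - best_score) <= 1e-12 and len(best) < max_cooptimal:
            best.setdefault(_canonical(topo), topo)
    topos = [best[k] for k in sorted(best)]
    return [Tree(t, list(aln.taxa), best_score) for t in topos]


def strict_consensus_bipartitions(trees: list[Tree]) -> set[frozenset]:
    """Bipartitions present in every co-optimal tree."""
    sets = [t.bipartitions() for t in trees]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def bootstrap_support(aln: SnpAlignment, n_reps: int = 100, seed: int = 0,
                      **search_kwargs) -> Tree:
    """Bootstrap branch support on the best full-data tree.

    Sites are resampled with replacement ``n_reps`` times (as per-site
    weights); a replicate supports a bipartition when the strict consensus
    of its optimal trees contains it. The first co-optimal full-data tree is
    returned with supports attached (percentages in [0, 100]).
    """
    base_trees = search_mp(aln, seed=seed, **search_kwargs)
    base = base_trees[0]
    counts: dict[frozenset, int] = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        weights = np.bincount(idx, minlength=aln.n_sites).astype(float)
        rep_trees = search_mp(aln, seed=int(rng.integers(2 ** 31)),
                              weights=weights, **search_kwargs)
        rep_bps = strict_consensus_bipartitions(rep_trees)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    base.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return base


def consensus_newick(trees: list[Tree]) -> str:
    """Strict consensus of co-optimal topologies, serialised via dendropy."""
    ns = dendropy.TaxonNamespace(trees[0].taxa)
    tl = dendropy.TreeList([t.to_dendropy(ns) for t in trees],
                           taxon_namespace=ns)
    cons = tl.consensus(min_freq=1.0)
    return cons.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# regional trees and clade classification
# ---------------------------------------------------------------------------

def haplotype_alignment(panel, interval) -> SnpAlignment:
    """Phased-haplotype alignment (two taxa per sample) over an interval."""
    if not panel.phased:
        raise ValueError("regional trees require a phased panel")
    pos0 = panel.sites["pos"].to_numpy() - 1
    on = ((panel.sites["chrom"] == interval.chrom).to_numpy()
          & (pos0 >= interval.start) & (pos0 < interval.end))
    taxa, rows = [], []
    for j, s in enumerate(panel.samples):
        colony = panel.colony_of[s]
        for k in (0, 1):
            alleles = panel.genotypes[on, j, k]
            if np.all(alleles < 0):
                continue
            taxa.append(f"{s}_{colony}_h{k}")
            rows.append(alleles)
    if len(taxa) < 4:
        raise ValueError("fewer than 4 haplotypes with data in region")
    return SnpAlignment(taxa, np.array(rows, dtype=np.int8))


def expand_region(call_interval, min_span: int = 1_000_000,
                  chrom_length: int | None = None):
    """Region for a per-inversion tree: the inversion span, symmetrically
    expanded about its midpoint to at least ``min_span``."""
    from .intervals import GenomicInterval

    if call_interval.length >= min_span:
        return call_interval
    mid = (call_interval.start + call_interval.end) // 2
    start = max(0, mid - min_span // 2)
    end = start + min_span
    if chrom_length is not None and end > chrom_length:
        end = chrom_length
        start = max(0, end - min_span)
    return GenomicInterval(call_interval.chrom, start, end)


def regional_tree(panel, call_interval, min_span: int = 1_000_000,
                  chrom_length: int | None = None, seed: int = 0,
                  **search_kwargs) -> Tree:
    """Parsimony tree of phased haplotypes over an inversion's region."""
    region = expand_region(call_interval, min_span, chrom_length)
    aln = haplotype_alignment(panel, region)
    return search_mp(aln, seed=seed, **search_kwargs)[0]


def representative_alignment(panel, seed: int = 0) -> SnpAlignment:
    """One representative sequence per sample from unphased genotypes:
    heterozygous calls take the majority allele, ties broken at random
    under ``seed``."""
    rng = np.random.default_rng(seed)
    g = panel.genotypes
    called = (g >= 0).all(axis=2)
    s = g.sum(axis=2)  # 0, 1 (het) or 2 where called
    rep = np.where(s >= 2, 1, 0).astype(np.int8)
    het = called & (s == 1)
    rep[het] = rng.integers(0, 2, size=int(het.sum()))
    rep[~called] = -1
    taxa = [f"{s_}_{panel.colony_of[s_]}" for s_ in panel.samples]
    return SnpAlignment(taxa, rep.T)


def classify_clade_introgression(tree: Tree, group_of: dict[str, str],
                                 outgroup_label: str = "outgroup"
                                 ) -> dict[str, str]:
    """Flag taxa nested inside a foreign group's smallest clade.

    The tree is read as rooted at the outgroup (any taxon whose group equals
    ``outgroup_label``); for each non-outgroup group G the smallest clade
    containing every G taxon is located, and non-G, non-outgroup taxa inside
    it are flagged with G — the operational signature of haplotype
    introgression. Returns {taxon: foreign group}.
    """
    groups = {group_of[t] for t in tree.taxa}
    if outgroup_label not in groups:
        raise ValueError("no outgroup taxon to root on")
    outs = {t for t in tree.taxa if group_of[t] == outgroup_label}
    all_taxa = set(tree.taxa)
    # clades on the outgroup-rooted tree: for each edge, the side not
    # containing the outgroup (edges splitting the outgroup give no clade)
    sides: list[set[str]] = []
    for s in tree.clade_sides():
        comp = all_taxa - s
        if not (s & outs):
            sides.append(s)
        elif not (comp & outs):
            sides.append(comp)
    sides.append(all_taxa - outs)
    flags: dict[str, str] = {}
    ingroup = all_taxa - outs
    for g in groups - {outgroup_label}:
        members = {t for t in tree.taxa if group_of[t] == g}
        containing = [s for s in sides if members <= s]
        smallest = min(containing, key=len)
        if smallest == ingroup:
            # the group's span is the whole ingroup: no informative nesting
            continue
        for t in smallest - members - outs:
            flags[t] = g
    return flags
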