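# Methods notes

This note records the scientific and numerical choices behind `linkinv`:
what each stage assumes, which knobs matter, what the synthetic data do and
do not emulate, and where the design was genuinely open.

## Site filtering and callsets

Sites are hard-filtered on GATK-style annotations with strict inequalities:
QD > 5, FS < 60, and a rank-sum cut that is applied to |ReadPosRankSum| < 8
by default. Rank-sum annotations are signed and a one-sided cut would keep
arbitrarily extreme negative values, which is almost never the intent of a
"RankSum < 8" rule; the literal signed reading is available via
`FilterConfig(ranksum_absolute=False)`, and MQRankSum can be supplied in
the same column if a caller emits that instead. Sites missing an annotation
are kept by default (GATK omits rank-sums at sites without heterozygotes);
`keep_missing_annotations=False` drops them. Only biallelic SNPs pass.

Two analysis callsets are derived: the *colony* callset (sites with at
least one fully called genotype in every colony — the per-colony count is
configurable, since no call-rate convention is universal) and the
*conserved* callset (additionally callable in every outgroup species
panel, with outgroup samples merged in for derived-allele polarisation).
Internal coordinates are 0-based half-open; VCF I/O converts at the
boundary. VCF annotations round-trip at float32 precision (htslib INFO
floats are 32-bit; the generator emits 2-decimal values, which serialise
exactly).

## Candidate merging

"95% pairwise overlap" is operationalised as *reciprocal* overlap — the
minimum of the two coverage fractions — because the symmetric reading is
the only one under which merging is order-invariant; a one-directional
variant can be had by lowering the threshold. Clustering is single-linkage
across samples and callers (a locus is one inversion regardless of which
caller or carrier reported it). The merged interval is the union span of
members; the representative breakpoints passed to validation are the
medians of member endpoints, which is robust to per-caller jitter.
Microinversion means size < 500 000 bp, strictly.

## Breakpoint validation

The validator treats inversion detection as a competitive read-assignment
problem. For a candidate `[s, e)` with flank F (default 10 000 bp — it must
comfortably exceed both the 1-kb span rule and half a typical read) four
junction contigs are built:

    bp1_ref = seq[s−F : s+F]            bp2_ref = seq[e−F : e+F]
    bp1_inv = seq[s−F : s] ++ revcomp(seq[e−F : e])
    bp2_inv = revcomp(seq[s : s+F]) ++ seq[e : e+F]

optionally alongside the chromosome with both native breakpoint
neighbourhoods masked to N. Reads longer than 5 kb are assigned to the
best-scoring contig; the orientation counts only when the alignment spans
at least 1 kb on both sides of the junction point (flank-only reads are
uninformative and are recorded `unassigned` — the dual-span rule is applied
before the tie rule). Exact score ties between the ref and inv contig of
one junction are `ambiguous` and excluded from both the numerator and the
denominator of the inverted fraction.

Decision thresholds (all configurable, defaults as published): coverage
≥ 10 assigned reads per breakpoint; coverage not above the upper Tukey
fence Q3 + 2×IQR of the null coverage distribution (the anchor of "2× the
inter-quartile range" is not standardised; the upper fence is the
conservative reading for a filter aimed at collapsed repeats, and a
both-tails flag exists); inverted fraction strictly above 0.37; both
breakpoints must pass. Quartiles use linear interpolation (type-7) — this
matters because IQR fences inherit the quartile convention.

The null is a set of artificial uninverted breakpoint pairs matched to the
candidates' flank repeat content (each null locus targets the repeat
fraction of a randomly chosen candidate within ±10 percentage points,
doubling the tolerance with a warning if matching stalls). Both junctions
of each pair contribute one observation, so 500 pairs give the published
1000-breakpoint null. The false-validation rate applies the *full*
decision rule to each null breakpoint.

### The built-in junction aligner

The default aligner indexes contigs with exact 15-mers; read k-mers
(sampled every 12 bases, both strands) vote for diagonals, and the winning
diagonal is scored by ungapped comparison (matches − 2×mismatches).
Junction contigs declare a *split point*: each side of the junction gets
its own best diagonal and the two segment scores are summed. This matters
because merged-call breakpoints carry caller jitter of tens of bases, which
offsets the two halves of a junction-spanning read relative to the contig —
a single-diagonal alignment would halve the score exactly where the signal
lives, while a gapped aligner (and the split scoring) absorbs it. Sides
whose diagonals disagree by more than 500 bp are treated as discordant and
only the better-supported side is kept. Hyper-repetitive seeds (> 50 index
hits) are skipped. The aligner assumes substitution-dominated errors, which
is what the read simulator produces; for externally generated reads with
indels the `Minimap2Aligner` adapter wraps the `minimap2` binary and
normalises PAF records to the same score scale.

Assembly validation classifies ordered alignment segments of reassembled
supercontigs (> 10 kb, per-segment score > 60): adjacent segments joining
the two upstream flanks (or the two downstream flanks) of the breakpoint
pair with opposite strands are the signature of an inverted junction;
assembly validates an inversion when both junctions are recovered across
supercontigs.

## Population statistics

π uses the unbiased per-site estimator 2p(1−p)·n/(n−1) summed over sites
and divided by the *window length* (1 Mb at full scale), matching the
common windowed-toolchain convention; a callable-sites denominator is
available behind a flag. ROH detection is a density scan (the reference
tool's internals are not published): windows of `min_length` (default
1 Mb) stepped at a tenth of the window pass when heterozygous-call density
is ≤ 5 per Mb (boundary included) and passing windows merge; the defaults
are chosen to flag the long founder-effect homozygosity blocks the
generator plants, not to segment ROH precisely.

F_st is Weir & Cockerham (1984) theta; windowed values are ratios of
summed variance components. Note the estimator is unbiased, not
non-negative: identical finite pools give slightly negative theta, and
monomorphic sites are reported missing rather than zero. AIMs require
pooled-subspecies theta strictly above 0.8, presence in both callsets, and
distinct pool-major alleles; "predominantly donor" in ancestry scoring
means donor-allele frequency strictly above 0.5, and uncallable AIM loci
drop out of the denominator. Founder-haplotype clustering is greedy in
descending length order against cluster representatives (the longest
member), joining at ≤ 1 difference per kb over ≥ 1 kb of overlap.

## Introgression

ABBA/BABA statistics use population allele frequencies (colonies hold
several diploids, so the frequency form wastes no data): per site,
ABBA = (1−p1)p2p3(1−pO) and BABA = p1(1−p2)p3(1−pO). The outgroup
polarises: frequencies are flipped where the outgroup alt frequency
exceeds 0.5 and sites with outgroup derived frequency > 0.1 are excluded.
Jackknife blocks are contiguous coordinate slabs (5 Mb at full scale,
500 kb at the generator's 1/100 toy scale — the block size is not stated
in the source analyses; blocks only need to exceed linkage scales);
SD = sqrt((m−1)/m · Σ(D₋ⱼ − mean)²), Z = D/SD, |Z| ≥ 2 significant, and a
zero SD yields a flagged undefined Z rather than an infinite one.

f_D replaces p2 and p3 by p_D = max(p2, p3) site-wise in the denominator;
windows are coordinate-based (1 Mb full scale) and windows with
non-positive numerator are missing. Note f_D is biased *downward* at small
pool sizes: with a handful of diploids per pool, sampling noise inflates
max(p2, p3) and hence the denominator, so tract-level means recover the
planted admixture fraction only up to a multiplicative factor — the
recovery tests therefore assert monotonicity and significance, not
equality. Peaks require a window to clear the global Tukey fence
(Q3 + 1.5×IQR over non-missing values) *and* reach 90% of the rolling
maximum over a centred 200-Mb (full scale) neighbourhood; adjacent
eligible windows merge. Both anchors ("1.5× the IQ range", "local maxima")
were underspecified in the source description; the Tukey fence and a
centred rolling maximum are the standard readings, with a median-anchored
alternative behind a flag.

## Phylogenies

Characters are binary; Fitch counts are computed with bitmask state sets
(missing = {0,1}, contributing no forced change) on an arbitrary rooting —
parsimony length is rooting-invariant, which the tests check. Unrooted
topologies are represented as rooted nested tuples over taxa 1..n−1 with
taxon 0 on the root edge. Search is exhaustive through 9 taxa. Above that,
stepwise addition (taxon order shuffled per restart) is followed by
iterated single-leaf re-insertion hill climbing — a move set chosen over
plain NNI because it is trivially correct on the nested-tuple
representation and strictly contains the NNI moves that involve a leaf;
three restarts by default. Co-optimal topologies are collected and reduced
to a strict consensus (via dendropy) for reporting; bootstrap replicates
resample site weights, and a replicate supports a bipartition when the
strict consensus of its optimal trees contains it.

Regional (per-inversion) trees use phased haplotypes over the inversion
span expanded symmetrically to at least 1 Mb; genome-wide trees use one
representative sequence per sample (heterozygous calls take the majority
allele, ties resolved at random under the seed). Clade-nesting
classification roots at the outgroup and flags non-members inside the
smallest clade containing a group — with one refinement: a group whose
smallest containing clade is the entire ingroup yields no flags, since the
"nesting" would be vacuous (this is also the only reading under which a
single grafted haplotype is flagged without symmetrically flagging the
entire host group).

## The synthetic study

The generator emulates a colony-based two-subspecies design at 1/100
coordinate scale: three 5-Mb chromosomes, 30% planted tandem-repeat
arrays (three motif families; the real genome is about two-thirds
repetitive), 1 SNP per 500 bp, eight colonies of 2–3 mosquitoes plus a
sister-species colony (26 samples), and two distant outgroup species for
polarisation. Subspecies allele frequencies drift from a common ancestor
by Balding–Nichols (defaults F_Aaa = 0.25 > F_Aaf = 0.12, giving the
lower Aaa diversity expected from its narrower founding; sister = 0.45,
outgroups = 0.85). Colony haplotypes are copies (mutation rate 5×10⁻⁴) of
a small founder pool, producing founder effects, long shared haplotypes,
and inbreeding-like homozygosity. Admixture events copy donor tracts into
*founder* haplotypes — colony founders were sampled from an already
hybridised population, so tracts are shared by every haplotype descending
from that founder; defaults mirror a bidirectional hybrid-zone pattern
(Aaf→Kenya-Aaa 0.30, Aaf→hybrid colony 0.35, Aaa→Kenya-Aaf 0.13). A
`shared` event mode plants one tract set carried by all founders (a
high-frequency introgressed region), and an `n_tracts` mode plants a fixed
number of fixed-length tracts round-robin across chromosomes — used by the
peak-recovery experiment, which needs a controlled number of
well-separated, window-scale planted signals (a windowed scan cannot, even
in principle, detect tracts much shorter than its window).

Inversions are spiked at configured sizes and colony frequencies at loci
whose breakpoint flanks are < 10% repeat (or > 50% for deliberate hard
cases); carriers have the segment reverse-complemented. Long reads are
log-normal with scale set analytically so the length-weighted median (N50)
matches the target (6789 bp default; the length-biased log-normal is again
log-normal, so mu = ln(N50) − sigma²), substitution errors at 5%, random
strand. Junction read sets measure the requested coverage in *selected*
(> 5 kb) reads, mirroring the longest-read selection step that precedes
alignment. Caller profiles detect carriers with size-class sensitivities,
jitter breakpoints (SD 30 bp / 80 bp), and emit false positives centred on
repeat arrays with caller-specific size spectra (the linked-read-style
caller smaller and more numerous, the assembly-style caller larger).

What the generator does **not** emulate: indel sequencing errors and
chimeric reads (the built-in aligner is substitution-oriented by design),
barcode-level linked-read molecule structure, gene conversion and
recombination within colonies, TE mobilisation, reference
misassembly, and SNP genotyping error beyond uniform missingness. Passing
recovery tests therefore demonstrate correctness of the statistical
machinery and the calibration logic under the stated read model, not
robustness to every artefact of real long-read data — for real data the
minimap2 adapter and externally called VCFs are the intended inputs.

## Validation experiments and problem sizes

The packaged experiments (in `linkinv.experiments`, used by the test suite
and by `scripts/acceptance.py`) run at these sizes, chosen to make each
quantity statistically meaningful at desk scale:

- **Null calibration**: full default study; 500 artificial pairs (1000
  junction breakpoints) in the reproduction script, 150 pairs in the test
  suite; ~30× selected reads per junction.
- **Inversion recall**: the 8 default spiked inversions, validated from up
  to three carrier samples each (an inversion is recalled if *any* carrier
  sample validates both junctions — matching a validation protocol in
  which reconstruction in some sample suffices); heterozygous carriers
  contribute 50/50 read mixtures.
- **D / f_D recovery**: a balanced four-colony quartet (4 samples, 8
  founders each) so the realised admixture fraction concentrates; admixture
  fractions 0, 0.15, 0.30.
- **Peak recovery**: three planted 500-kb shared tracts, one per
  chromosome; 250-kb windows, 2-Mb locality (1/100 of full scale).
- **Bootstrap recovery**: five colonies, 7 representative taxa, 1000
  sites, 100 replicates.

## Known limitations

- The ROH scanner reports window-granular boundaries, not exact
  breakpoints.
- The built-in aligner requires exact k-mer seeds; above ~15% divergence
  or with indel-rich reads it loses sensitivity (use the minimap2
  adapter).
- Heuristic tree search guarantees only local optimality above 9 taxa;
  bootstrap on many taxa is the dominant cost and the pipeline therefore
  subsamples one representative per colony for the genome tree.
- f_D's small-sample downward bias (above) means tract-level admixture
  fractions are rank-informative, not calibrated estimates.
- The pipeline's validation stage simulates reads for the calling
  samples' haplotypes; plugging in real read sets requires supplying
  per-region FASTA/FASTQ through the library API.
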