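"""Genotype panels, site-level filtering, callset construction, and VCF I/O.

The in-memory container is :class:`GenotypePanel`: a site table (pandas) plus
a ``(n_sites, n_samples, 2)`` int8 genotype array, with ``-1`` marking a
missing allele call. Sample-to-colony and colony-to-role metadata travel with
the panel so that downstream population statistics can address samples by
colony.

Filtering reproduces the hard GATK-annotation cuts used for single-mosquito
linked-read callsets: QD > 5, FS < 60, |ReadPosRankSum| < 8, biallelic SNPs
only. Two analysis callsets are derived: a *colony* callset (sites callable
in every colony) and a *conserved* callset (additionally callable in every
outgroup species panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

ANNOTATION_COLUMNS = ("qd", "fs", "ranksum")
MISSING = -1


@dataclass
class FilterConfig:
    """Thresholds for site-level quality filtering (strict inequalities)."""

    qd: float = 5.0
    fs: float = 60.0
    ranksum: float = 8.0
    #: interpret the rank-sum cut on |value| (signed annotations); set False
    #: for the literal one-sided reading ``value < threshold``.
    ranksum_absolute: bool = True
    #: keep sites where an annotation is missing (GATK emits no RankSum at
    #: sites without heterozygotes); set False to drop them.
    keep_missing_annotations: bool = True


@dataclass
class GenotypePanel:
    """Biallelic SNP sites with per-sample diploid genotypes.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt, qd, fs, ranksum`` — ``pos`` is
        1-based (VCF convention); annotation columns are float32 with NaN
        for missing. Sorted by (chrom, pos).
    genotypes : numpy.ndarray
        ``(n_sites, n_samples, 2)`` int8 allele indices, -1 = missing.
    samples : list of str
    colony_of : dict
        sample -> colony.
    role_of : dict
        colony -> role label (subspecies tag such as ``Aaa``/``Aaf``,
        ``hybrid``, ``sister``, ``outgroup``).
    phased : bool
        Whether ``genotypes[..., 0]``/``[..., 1]`` are haplotype-resolved.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    colony_of: dict[str, str]
    role_of: dict[str, str] = field(default_factory=dict)
    phased: bool = False

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if self.genotypes.shape[:2] != (len(self.sites), len(self.samples)):
            raise ValueError("genotype array shape does not match sites/samples")
        missing = [s for s in self.samples if s not in self.colony_of]
        if missing:
            raise ValueError(f"samples without colony assignment: {missing}")
        order = np.lexsort((self.sites["pos"].to_numpy(),
                            self.sites["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[order]

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def colonies(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.colony_of[s], None)
        return list(seen)

    def colony_samples(self, colony: str) -> list[str]:
        return [s for s in self.samples if self.colony_of[s] == colony]

    def sample_indices(self, samples: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc}") from exc

    def subset_sites(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(self, sites=self.sites.iloc[idx], genotypes=self.genotypes[idx])

    # -- allele frequencies ------------------------------------------------
    def allele_counts(self, samples: list[str] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) for a sample set."""
        g = self.genotypes
        if samples is not None:
            g = g[:, self.sample_indices(samples), :]
        called = g >= 0
        alt = ((g == 1) & called).sum(axis=(1, 2))
        return alt, called.sum(axis=(1, 2))

    def allele_frequency(self, samples: list[str] | None = None) -> np.ndarray:
        """Per-site alt-allele frequency (NaN where no calls)."""
        alt, n = self.allele_counts(samples)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def colony_frequency(self, colony: str) -> np.ndarray:
        return self.allele_frequency(self.colony_samples(colony))


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def site_filter_mask(sites: pd.DataFrame, config: FilterConfig | None = None
                     ) -> np.ndarray:
    """Boolean retain-mask applying the quality cuts to a site table.

    A site passes iff QD > qd, FS < fs, RankSum within the rank-sum cut
    (|value| < threshold by default), and the record is a biallelic SNP
    (single-base ref and alt). Thresholds are strict.
    """
    config = config or FilterConfig()
    n = len(sites)
    keep = np.ones(n, dtype=bool)

    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    keep &= (ref.str.len() == 1).to_numpy()
    keep &= (alt.str.len() == 1).to_numpy()
    keep &= (~alt.str.contains(",")).to_numpy()

    def _cut(values: np.ndarray, ok: np.ndarray) -> np.ndarray:
        miss = np.isnan(values)
        return np.where(miss, config.keep_missing_annotations, ok)

    qd = sites["qd"].to_numpy(dtype=float)
    fs = sites["fs"].to_numpy(dtype=float)
    rs = sites["ranksum"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep &= _cut(qd, qd > config.qd)
        keep &= _cut(fs, fs < config.fs)
        if config.ranksum_absolute:
            keep &= _cut(rs, np.abs(rs) < config.ranksum)
        else:
            keep &= _cut(rs, rs < config.ranksum)
    return keep


def filter_sites(panel: GenotypePanel, config: FilterConfig | None = None
                 ) -> GenotypePanel:
    """Return the panel restricted to sites passing :func:`site_filter_mask`."""
    return panel.subset_sites(site_filter_mask(panel.sites, config))


# ---------------------------------------------------------------------------
# callsets
# ---------------------------------------------------------------------------

def _site_key(sites: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(sites[["chrom", "pos", "ref", "alt"]])


def _called_in_every_colony(panel: GenotypePanel, min_called: int) -> np.ndarray:
    ok = np.ones(panel.n_sites, dtype=bool)
    for colony in panel.colonies():
        idx = panel.sample_indices(panel.colony_samples(colony))
        called = (panel.genotypes[:, idx, :] >= 0).all(axis=2).sum(axis=1)
        ok &= called >= min_called
    return ok


def build_callsets(panel: GenotypePanel,
                   outgroup_panels: list[GenotypePanel],
                   min_called_per_colony: int = 1
                   ) -> tuple[GenotypePanel, GenotypePanel]:
    """Build the colony and conserved analysis callsets.

    colony callset
        sites of ``panel`` with at least ``min_called_per_colony`` fully
        called genotypes in every colony.
    conserved callset
        the subset of the colony callset additionally callable (same
        criterion) in every outgroup panel; outgroup samples are appended to
        the returned panel so derived-allele polarisation can use them.

    The conserved site list is a subset of the colony site list by
    construction.
    """
    import warnings

    colony = panel.subset_sites(_called_in_every_colony(panel, min_called_per_colony))
    if colony.n_sites == 0:
        warnings.warn("colony callset is empty", stacklevel=2)

    keep = np.ones(colony.n_sites, dtype=bool)
    key = _site_key(colony.sites)
    aligned_genotypes = [colony.genotypes]
    samples = list(colony.samples)
    colony_of = dict(colony.colony_of)
    role_of = dict(colony.role_of)
    for og in outgroup_panels:
        og_ok = og.subset_sites(_called_in_every_colony(og, min_called_per_colony))
        og_key = _site_key(og_ok.sites)
        pos = og_key.get_indexer(key)  # -1 where absent
        keep &= pos >= 0
        g = np.full((colony.n_sites, og_ok.n_samples, 2), MISSING, dtype=np.int8)
        found = pos >= 0
        g[found] = og_ok.genotypes[pos[found]]
        aligned_genotypes.append(g)
        samples.extend(og_ok.samples)
        colony_of.update(og_ok.colony_of)
        role_of.update(og_ok.role_of)

    conserved = GenotypePanel(
        sites=colony.sites.loc[keep],
        genotypes=np.concatenate(aligned_genotypes, axis=1)[keep],
        samples=samples,
        colony_of=colony_of,
        role_of=role_of,
        phased=False,
    )
    if conserved.n_sites == 0:
        warnings.warn("conserved callset is empty", stacklevel=2)
    return colony, conserved


# ---------------------------------------------------------------------------
# VCF and metadata I/O
# ---------------------------------------------------------------------------

_INFO_FIELDS = {"qd": "QD", "fs": "FS", "ranksum": "ReadPosRankSum"}


def write_vcf(panel: GenotypePanel, path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a panel to an uncompressed VCF 4.2 file (GT + QD/FS/ReadPosRankSum)."""
    header = pysam.VariantHeader()
    if contig_lengths is None:
        contig_lengths = {
            c: int(panel.sites.loc[panel.sites["chrom"] == c, "pos"].max()) + 1
            for c in pd.unique(panel.sites["chrom"])
        }
    for chrom, length in contig_lengths.items():
        header.contigs.add(str(chrom), length=length)
    for tag in _INFO_FIELDS.values():
        header.info.add(tag, number=1, type="Float", description=tag)
    header.formats.add("GT", number=1, type="String", description="Genotype")
    for s in panel.samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i in range(panel.n_sites):
            row = panel.sites.iloc[i]
            rec = vcf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for col, tag in _INFO_FIELDS.items():
                v = row[col]
                if pd.notna(v):
                    rec.info[tag] = float(v)
            for j, s in enumerate(panel.samples):
                a0, a1 = panel.genotypes[i, j]
                gt = (None if a0 < 0 else int(a0), None if a1 < 0 else int(a1))
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = panel.phased
            vcf.write(rec)


def read_vcf(path: str, colony_of: dict[str, str],
             role_of: dict[str, str] | None = None,
             phased: bool = False) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Multi-allelic records are kept (alt alleles joined with commas) so that
    :func:`filter_sites` can drop them by rule rather than silently; records
    with a malformed GT raise with the site coordinates in the message.
    """
    rows = []
    gts = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            row = {
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": ",".join(alts) if alts else ".",
            }
            for col, tag in _INFO_FIELDS.items():
                v = rec.info.get(tag)
                row[col] = np.float32(v) if v is not None else np.nan
            rows.append(row)
            site_gt = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                if len(gt) != 2:
                    raise ValueError(
                        f"malformed genotype for {s} at {rec.chrom}:{rec.pos}")
                for k, a in enumerate(gt):
                    if a is not None:
                        site_gt[j, k] = a
            gts.append(site_gt)

    sites = pd.DataFrame(rows)
    for col in ANNOTATION_COLUMNS:
        sites[col] = sites[col].astype(np.float32)
    genotypes = (np.stack(gts) if gts
                 else np.empty((0, len(samples), 2), dtype=np.int8))
    return GenotypePanel(sites=sites, genotypes=genotypes, samples=samples,
                         colony_of=dict(colony_of),
                         role_of=dict(role_of or {}), phased=phased)


def read_metadata(path: str) -> tuple[dict[str, str], dict[str, str]]:
    """Read a sample metadata TSV (columns: sample, colony, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    colony_of = dict(zip(df["sample"], df["colony"]))
    role_of = dict(zip(df["colony"], df["role"]))
    return colony_of, role_of


def write_metadata(panel: GenotypePanel, path: str) -> None:
    rows = [(s, panel.colony_of[s], panel.role_of.get(panel.colony_of[s], ""))
            for s in panel.samples]
    pd.DataFrame(rows, columns=["sample", "colony", "role"]).to_csv(
        path, sep="\t", index=False)
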