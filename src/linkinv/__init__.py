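"""linkinv: inversion discovery, long-read breakpoint validation, and
introgression analysis for linked-read mosquito genomics."""

from importlib import resources

import pandas as pd

from .intervals import GenomicInterval, reciprocal_overlap
from .genomics_io import (FilterConfig, GenotypePanel, build_callsets,
                          filter_sites, read_vcf, write_vcf)
from .sv_merge import (InversionCall, InversionCandidate, classify_and_count,
                       merge_candidates)
from .breakpoints import (BreakpointPair, NullCalibration, PanGenome,
                          assign_reads, build_pangenome, calibrate_null,
                          generate_artificial_breakpoints, validate_inversion)
from .simulate import SimConfig, simulate_all

__version__ = "0.1.0"


def load_inversion_catalog() -> pd.DataFrame:
    """The published catalog of 32 validated *Aedes aegypti* inversions
    (coordinates 1-based inclusive as printed; size = end - start)."""
    with resources.files("linkinv.data").joinpath(
            "inversion_catalog.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


__all__ = [
    "GenomicInterval", "reciprocal_overlap",
    "FilterConfig", "GenotypePanel", "build_callsets", "filter_sites",
    "read_vcf", "write_vcf",
    "InversionCall", "InversionCandidate", "classify_and_count",
    "merge_candidates",
    "BreakpointPair", "NullCalibration", "PanGenome", "assign_reads",
    "build_pangenome", "calibrate_null", "generate_artificial_breakpoints",
    "validate_inversion",
    "SimConfig", "simulate_all",
    "load_inversion_catalog",
]
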