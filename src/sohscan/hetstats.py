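"""Per-genome summary statistics: depth-based scaffold QC, overall
heterozygosity and allelic balance."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from sohscan.errors import UndefinedValueError
from sohscan.vcfio import VariantRecord

# Scaffolds outside 0.5-2x of the genome-wide average depth are excluded
# (sex chromosomes, collapsed repeats); only scaffolds > 10 kb are analysed.
DEPTH_LO_FACTOR = 0.5
DEPTH_HI_FACTOR = 2.0
MIN_SCAFFOLD_LEN_EXCLUSIVE = 10_000


@dataclass
class GenomeSummary:
    """Single-genome diversity summary."""

    species: str
    overall_het: float
    callable_bp: int
    callable_pct: float
    mean_ab: float
    n_het_sites: int
    contig_n50: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def filter_scaffolds_by_depth(
    scaffolds: pd.DataFrame,
    min_length_exclusive: int = MIN_SCAFFOLD_LEN_EXCLUSIVE,
) -> pd.DataFrame:
    """Keep scaffolds with depth in [0.5, 2] x the length-weighted mean.

    The genome-wide average depth is the length-weighted mean over the
    *input* scaffolds (so it matches an average over mapped coverage).
    Scaffolds at exactly 0.5x or 2x are kept ("less than 0.5x" and
    "greater than 2x" are the exclusion rules). Scaffolds of length
    <= `min_length_exclusive` bp are dropped regardless of depth.
    """
    if len(scaffolds) == 0:
        raise UndefinedValueError("empty scaffold table")
    lengths = scaffolds["length"].to_numpy(dtype=float)
    depths = scaffolds["mean_depth"].to_numpy(dtype=float)
    mean_depth = float(np.average(depths, weights=lengths))
    keep = (
        (depths >= DEPTH_LO_FACTOR * mean_depth)
        & (depths <= DEPTH_HI_FACTOR * mean_depth)
        & (lengths > min_length_exclusive)
    )
    return scaffolds.loc[keep].reset_index(drop=True)


def overall_heterozygosity(n_het_sites: int, callable_bp: int) -> float:
    """Heterozygous calls per callable bp (global heterozygosity).

    `n_het_sites` should count high-confidence heterozygous calls on
    depth-filtered scaffolds; `callable_bp` is the callable genome length
    on the same scaffolds.
    """
    if callable_bp <= 0:
        raise UndefinedValueError("callable_bp must be positive")
    if n_het_sites < 0:
        raise ValueError("n_het_sites must be >= 0")
    return n_het_sites / callable_bp


def mean_allelic_balance(records: Iterable[VariantRecord]) -> float:
    """Mean per-site allelic imbalance over heterozygous calls.

    Per site b = |ref_reads - alt_reads| / (ref_reads + alt_reads); the
    returned score is the unweighted mean of b, in [0, 1], with 0 meaning
    perfectly balanced read support. Sites without usable AD (missing or
    summing to zero) are skipped.
    """
    vals = []
    for r in records:
        if r.ad is None:
            continue
        ref, alt = r.ad
        tot = ref + alt
        if tot <= 0:
            continue
        vals.append(abs(ref - alt) / tot)
    if not vals:
        raise UndefinedValueError("no heterozygous sites with usable AD")
    return float(np.mean(vals))


def summarize_genome(
    species: str,
    het_records: Iterable[VariantRecord],
    callable_bp: int,
    assembly_bp: int,
    contig_n50: int | None = None,
) -> GenomeSummary:
    """Assemble a :class:`GenomeSummary` from filtered inputs."""
    recs = list(het_records)
    het = overall_heterozygosity(len(recs), callable_bp)
    try:
        ab = mean_allelic_balance(recs)
    except UndefinedValueError:
        ab = float("nan")
    return GenomeSummary(
        species=species,
        overall_het=het,
        callable_bp=callable_bp,
        callable_pct=100.0 * callable_bp / assembly_bp if assembly_bp else float("nan"),
        mean_ab=ab,
        n_het_sites=len(recs),
        contig_n50=contig_n50,
    )
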