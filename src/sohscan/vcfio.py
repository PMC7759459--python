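"""VCF / BED input-output and site-level genotype filters.

All internal interval arithmetic is 0-based half-open; VCF positions are
1-based and converted only at the I/O boundary. Variant streams carry the
GT:AD:DP:GQ dialect used for single-sample diploid callsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from sohscan.errors import VcfParseError

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")

# High-confidence heterozygous-site thresholds: GQ strictly above 20,
# depth strictly between 6 and 100 reads.
GQ_MIN_EXCLUSIVE = 20
DP_MIN_EXCLUSIVE = 6
DP_MAX_EXCLUSIVE = 100

# Callable-genome threshold: positions with genotype quality above 15.
CALLABLE_GQ_MIN_EXCLUSIVE = 15


@dataclass(frozen=True)
class VariantRecord:
    """One genotype call at a site.

    Attributes
    ----------
    scaffold : str
        Scaffold (contig) identifier.
    pos : int
        1-based position, as printed in a VCF.
    ref, alt : str
        Reference and alternate alleles.
    genotype : str
        One of ``hom_ref``, ``het``, ``hom_alt``, ``missing``. A call with
        two distinct alleles (including two distinct alternates) is ``het``.
    gq : int or None
        Phred-scaled genotype quality; ``None`` when absent.
    dp : int or None
        Read depth; ``None`` when absent.
    ad : (int, int) or None
        Reads supporting (ref, alt); ``None`` when absent.
    """

    scaffold: str
    pos: int
    ref: str
    alt: str
    genotype: str
    gq: int | None = None
    dp: int | None = None
    ad: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.ad is not None and (self.ad[0] < 0 or self.ad[1] < 0):
            raise ValueError(f"AD components must be >= 0, got {self.ad}")

    @property
    def start0(self) -> int:
        """0-based start of the 1-bp interval covered by this site."""
        return self.pos - 1


class CallableMask:
    """Per-scaffold sets of callable intervals, 0-based half-open.

    Intervals are stored sorted and merged; ``total_bp`` is the summed
    length over all scaffolds.
    """

    def __init__(self, intervals: Mapping[str, np.ndarray | list] | None = None):
        self._ivs: dict[str, np.ndarray] = {}
        if intervals:
            for scaf, arr in intervals.items():
                self._ivs[scaf] = merge_intervals(np.asarray(arr, dtype=np.int64))

    @property
    def scaffolds(self) -> list[str]:
        return list(self._ivs)

    def intervals(self, scaffold: str) -> np.ndarray:
        """Merged (n, 2) interval array for one scaffold (empty if absent)."""
        return self._ivs.get(scaffold, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._ivs.values()))

    def overlap_bp(self, scaffold: str, start: int, end: int) -> int:
        """Callable bp inside [start, end) on one scaffold."""
        iv = self.intervals(scaffold)
        if len(iv) == 0:
            return 0
        lo = np.maximum(iv[:, 0], start)
        hi = np.minimum(iv[:, 1], end)
        return int(np.maximum(hi - lo, 0).sum())

    def contains(self, scaffold: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        iv = self.intervals(scaffold)
        if len(iv) == 0:
            return False
        i = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < iv[i, 1]

    def clip_to_bounds(self, lengths: Mapping[str, int]) -> "CallableMask":
        """Intersect with scaffold [0, length) bounds; never grows total_bp."""
        out: dict[str, np.ndarray] = {}
        for scaf, iv in self._ivs.items():
            if scaf not in lengths:
                continue
            clipped = np.clip(iv, 0, int(lengths[scaf]))
            out[scaf] = clipped[clipped[:, 1] > clipped[:, 0]]
        return CallableMask(out)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for scaf in self._ivs:
                for s, e in self._ivs[scaf]:
                    fh.write(f"{scaf}\t{s}\t{e}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "CallableMask":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["scaffold", "start", "end"], dtype={0: str},
        )
        grouped: dict[str, np.ndarray] = {
            scaf: sub[["start", "end"]].to_numpy(dtype=np.int64)
            for scaf, sub in df.groupby("scaffold", sort=False)
        }
        return cls(grouped)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallableMask):
            return NotImplemented
        if set(self._ivs) != set(other._ivs):
            return False
        return all(np.array_equal(self._ivs[k], other._ivs[k]) for k in self._ivs)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent 0-based half-open intervals."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.array(merged, dtype=np.int64)


def _classify_gt(alleles: tuple) -> str:
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return "missing"
    distinct = set(alleles)
    if len(distinct) > 1:
        return "het"  # any two distinct alleles, multi-allelic included
    return "hom_ref" if alleles[0] == 0 else "hom_alt"


def read_vcf(path: str | Path) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` from a single-sample VCF.

    Missing FORMAT keys yield records with the corresponding field ``None``.
    A malformed record raises :class:`VcfParseError` naming the line.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    n_header = len(str(vf.header).splitlines())
    it = iter(vf)
    idx = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as exc:
            raise VcfParseError(
                f"{path}: malformed record at line {n_header + idx + 1}: {exc}"
            ) from exc
        idx += 1
        if not rec.samples:
            raise VcfParseError(
                f"{path}: record at line {n_header + idx} carries no sample"
            )
        smp = rec.samples[0]
        gt = smp.get("GT")
        ad_raw = smp.get("AD")
        ad = None
        if ad_raw is not None and len(ad_raw) >= 2 and ad_raw[0] is not None:
            ad = (int(ad_raw[0]), int(ad_raw[1]))
        gq = smp.get("GQ")
        dp = smp.get("DP")
        yield VariantRecord(
            scaffold=rec.chrom,
            pos=rec.pos,
            ref=rec.ref or "N",
            alt=rec.alts[0] if rec.alts else ".",
            genotype=_classify_gt(gt),
            gq=int(gq) if gq is not None else None,
            dp=int(dp) if dp is not None else None,
            ad=ad,
        )


_GT_CODE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1), "missing": (None, None)}


def write_vcf(
    records: Iterable[VariantRecord],
    scaffolds: pd.DataFrame,
    path: str | Path,
    sample: str = "SAMPLE",
) -> None:
    """Write records as VCF v4.2 with FORMAT GT:AD:DP:GQ.

    `scaffolds` must carry columns ``scaffold`` and ``length`` for the
    contig header lines. Fields the dialect does not cover are dropped
    with a logged warning.
    """
    header = pysam.VariantHeader()
    for _, row in scaffolds.iterrows():
        header.contigs.add(str(row["scaffold"]), length=int(row["length"]))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.scaffold, start=r.pos - 1, stop=r.pos,
                alleles=(r.ref, r.alt),
            )
            smp = rec.samples[sample]
            smp["GT"] = _GT_CODE[r.genotype]
            if r.ad is not None:
                smp["AD"] = r.ad
            if r.dp is not None:
                smp["DP"] = r.dp
            if r.gq is not None:
                smp["GQ"] = r.gq
            out.write(rec)


@dataclass
class FilterResult:
    """High-confidence filter output: kept records plus a drop tally."""

    records: list[VariantRecord]
    dropped: dict[str, int]

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def filter_high_confidence(records: Iterable[VariantRecord]) -> FilterResult:
    """Keep heterozygous calls with GQ > 20 and 6 < DP < 100.

    All bounds are strict. Records missing GQ or DP are excluded and
    tallied under ``missing_fields``. Order is preserved; the filter is
    idempotent.
    """
    kept: list[VariantRecord] = []
    dropped = {"not_het": 0, "missing_fields": 0, "gq": 0, "dp": 0}
    for r in records:
        if r.genotype != "het":
            dropped["not_het"] += 1
        elif r.gq is None or r.dp is None:
            dropped["missing_fields"] += 1
        elif r.gq <= GQ_MIN_EXCLUSIVE:
            dropped["gq"] += 1
        elif not (DP_MIN_EXCLUSIVE < r.dp < DP_MAX_EXCLUSIVE):
            dropped["dp"] += 1
        else:
            kept.append(r)
    return FilterResult(kept, dropped)


def callable_mask_from_gq(
    track: Iterable[tuple[str, int, int, int]],
    gq_min_exclusive: int = CALLABLE_GQ_MIN_EXCLUSIVE,
) -> CallableMask:
    """Build the callable mask from a banded genotype-quality track.

    `track` yields (scaffold, start, end, gq) with 0-based half-open
    coordinates, as produced by gVCF quality banding (bands 0/10/20/30/
    40/50/99). The mask is the merged union of bands with GQ above the
    threshold (default 15, so band >= 20 is callable). Overlapping input
    bands are merged with a warning.
    """
    per_scaf: dict[str, list[list[int]]] = {}
    total_in = 0
    for scaf, start, end, gq in track:
        if end <= start:
            continue
        if gq > gq_min_exclusive:
            per_scaf.setdefault(scaf, []).append([start, end])
            total_in += end - start
    mask = CallableMask({k: np.array(v) for k, v in per_scaf.items()})
    if mask.total_bp < total_in:
        warnings.warn(
            f"overlapping GQ bands merged ({total_in - mask.total_bp} bp overlap)",
            stacklevel=2,
        )
    return mask
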