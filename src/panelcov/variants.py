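"""Variant catalogue partitioning and per-position detectability binning.

A catalogued variant either has a genomic coordinate ("positional") or is a
large insertion/deletion reported without one; coordinate-free records
cannot be assessed by per-base depth and are surfaced separately, never
binned.  Positional records are collapsed to unique (chrom, pos) positions
for depth statistics: a position sequenced at good depth is detectable
regardless of which base change is reported there, so positions with
multiple reported alleles share one detectability record (per-record rows
are still emitted).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import pct
from .intervals import CaptureDesign, ExonLocator, GenePanel

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "VariantRecord",
    "CataloguePartition",
    "partition_catalogue",
    "unique_positions",
    "DepthBin",
    "DetectabilityBins",
    "depth_at",
    "DetectabilityRecord",
    "DetectabilityResult",
    "detectability",
]

PATHOGENICITY_LEVELS = ("pathogenic", "likely_pathogenic", "VUS", "unknown")


class VariantClass(str, enum.Enum):
    POSITIONAL = "positional"
    LARGE_INDEL = "large_indel_no_coordinate"


@dataclass(frozen=True)
class VariantRecord:
    """One catalogued variant, pathogenicity label carried verbatim."""

    variant_id: str
    gene: str
    variant_class: VariantClass
    chrom: str | None = None
    pos: int | None = None  # 1-based
    ref: str = ""
    alt: str = ""
    hgvs_c: str = ""
    pathogenicity: str = "unknown"

    def __post_init__(self) -> None:
        has_coord = self.chrom is not None and self.pos is not None
        if self.variant_class is VariantClass.POSITIONAL:
            if not has_coord:
                raise ValueError(
                    f"positional variant {self.variant_id!r} lacks chrom/pos"
                )
            if self.pos is not None and self.pos < 1:
                raise ValueError(
                    f"variant {self.variant_id!r}: 1-based pos must be >= 1"
                )
        else:
            if self.chrom is not None or self.pos is not None:
                raise ValueError(
                    f"coordinate-free variant {self.variant_id!r} must not "
                    "carry chrom/pos"
                )
        if self.pathogenicity not in PATHOGENICITY_LEVELS:
            raise ValueError(
                f"variant {self.variant_id!r}: unknown pathogenicity "
                f"{self.pathogenicity!r}"
            )


@dataclass(frozen=True)
class CataloguePartition:
    """Counts of a catalogue split by class and position multiplicity."""

    n_total: int
    n_large_indel: int
    n_positional: int
    n_unique_positions: int
    n_multiallelic_positions: int

    def __post_init__(self) -> None:
        if self.n_large_indel + self.n_positional != self.n_total:
            raise ValueError("class counts must sum to the total")
        if self.n_multiallelic_positions > self.n_unique_positions:
            raise ValueError("multiallelic positions cannot exceed unique positions")

    # percentage views mirror the usual report denominators: classes over
    # all records, position multiplicity over positional records
    @property
    def pct_large_indel(self) -> float:
        return pct(self.n_large_indel, self.n_total)

    @property
    def pct_positional(self) -> float:
        return pct(self.n_positional, self.n_total)

    @property
    def pct_unique_position(self) -> float:
        return pct(self.n_unique_positions, self.n_positional)

    @property
    def pct_multiallelic(self) -> float:
        return pct(self.n_multiallelic_positions, self.n_positional)


def unique_positions(records: Iterable[VariantRecord]) -> list[tuple[str, int]]:
    """Sorted distinct (chrom, 1-based pos) among positional records."""
    return sorted(
        {
            (r.chrom, r.pos)
            for r in records
            if r.variant_class is VariantClass.POSITIONAL
        }
    )


def partition_catalogue(records: Sequence[VariantRecord]) -> CataloguePartition:
    """Split a catalogue by class and count unique / multiallelic positions.

    Order-invariant and deterministic: positions are grouped by exact
    (chrom, pos) equality; a position is multiallelic when two or more
    distinct records are reported there.
    """
    n_total = len(records)
    n_large = sum(
        1 for r in records if r.variant_class is VariantClass.LARGE_INDEL
    )
    counts: dict[tuple[str, int], int] = {}
    for r in records:
        if r.variant_class is VariantClass.POSITIONAL:
            counts[(r.chrom, r.pos)] = counts.get((r.chrom, r.pos), 0) + 1
    return CataloguePartition(
        n_total=n_total,
        n_large_indel=n_large,
        n_positional=n_total - n_large,
        n_unique_positions=len(counts),
        n_multiallelic_positions=sum(1 for c in counts.values() if c >= 2),
    )


# ---------------------------------------------------------------------------
# depth bins


class DepthBin(str, enum.Enum):
    ADEQUATE = "adequate"  # depth >= threshold
    MID = "10-19x"  # 10 <= depth < threshold
    LOW = "5-9x"  # 5 <= depth < 10
    VERY_LOW = "<5x"  # depth < 5

BIN_ORDER = [DepthBin.ADEQUATE, DepthBin.MID, DepthBin.LOW, DepthBin.VERY_LOW]


@dataclass(frozen=True)
class DetectabilityBins:
    """Depth strata for judging whether a variant call would be made.

    The adequate stratum starts at `depth_threshold` (inclusive, default
    20); the fixed lower edges at 10 and 5 reads mirror the cutoffs relaxed
    analysis pipelines use.  The four bins partition the non-negative
    integers exactly, which requires depth_threshold > 10.
    """

    depth_threshold: int = 20

    def __post_init__(self) -> None:
        if self.depth_threshold <= 10:
            raise ValueError("depth_threshold must exceed the fixed 10x bin edge")

    def bin(self, depth: int) -> DepthBin:
        if depth < 0:
            raise ValueError("depth must be non-negative")
        if depth >= self.depth_threshold:
            return DepthBin.ADEQUATE
        if depth >= 10:
            return DepthBin.MID
        if depth >= 5:
            return DepthBin.LOW
        return DepthBin.VERY_LOW


def depth_at(profile, chrom: str, pos1: int) -> int:
    """Sample depth at a 1-based position; 0 (logged) outside the footprint."""
    if pos1 < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos1}")
    i = profile.footprint.index(chrom, pos1 - 1)
    if i < 0:
        logger.debug("%s:%d outside panel footprint; depth 0", chrom, pos1)
        return 0
    return int(profile.depth[i])


# ---------------------------------------------------------------------------
# detectability


@dataclass(frozen=True)
class DetectabilityRecord:
    """Detectability of one unique catalogued position."""

    chrom: str
    pos: int  # 1-based
    variant_ids: tuple[str, ...]
    exon_ids: tuple[str, ...]
    captured: bool
    summary_depth: int
    bin: DepthBin


@dataclass
class DetectabilityResult:
    positions: list[DetectabilityRecord]
    excluded: list[DetectabilityRecord] = field(default_factory=list)  # outside panel
    large_indels: list[VariantRecord] = field(default_factory=list)

    @property
    def bin_counts(self) -> dict[DepthBin, int]:
        out = {b: 0 for b in BIN_ORDER}
        for rec in self.positions:
            out[rec.bin] += 1
        return out

    @property
    def n_captured(self) -> int:
        return sum(1 for rec in self.positions if rec.captured)

    def per_variant_rows(self) -> list[dict]:
        """One row per catalogue record (positions expanded back out)."""
        rows = []
        for rec in self.positions:
            for vid in rec.variant_ids:
                rows.append(
                    {
                        "variant_id": vid,
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "captured": rec.captured,
                        "summary_depth": rec.summary_depth,
                        "depth_bin": rec.bin.value,
                    }
                )
        return rows


def detectability(
    records: Iterable[VariantRecord],
    profiles: Sequence,
    panel: GenePanel,
    design: CaptureDesign | None = None,
    capture_report=None,
    bins: DetectabilityBins | None = None,
    summary: str = "mean",
) -> DetectabilityResult:
    """Bin every unique catalogued position by its summary sequencing depth.

    The per-position summary depth is the chosen statistic (arithmetic mean
    by default, median by config) of the per-sample depths, rounded down to
    an integer.  A position is flagged captured when at least one exon
    containing it is captured by the design (the capture report may be
    passed in to reuse flags already computed).  Positions falling in no
    panel exon are excluded from bin aggregates and reported separately;
    coordinate-free large indels are never binned.
    """
    if not profiles:
        raise ValueError("at least one depth profile is required")
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary statistic {summary!r}")
    if bins is None:
        bins = DetectabilityBins()
    records = list(records)
    large = [r for r in records if r.variant_class is VariantClass.LARGE_INDEL]
    positional = [r for r in records if r.variant_class is VariantClass.POSITIONAL]

    if capture_report is not None:
        captured_ids = {
            eid for eid, flag in capture_report.exon_captured.items() if flag
        }
    elif design is not None:
        from .capture import assess_capture

        rep = assess_capture(panel, design)
        captured_ids = {eid for eid, flag in rep.exon_captured.items() if flag}
    else:
        raise ValueError("either design or capture_report must be given")

    by_pos: dict[tuple[str, int], list[str]] = {}
    for r in positional:
        by_pos.setdefault((r.chrom, r.pos), []).append(r.variant_id)

    locator = ExonLocator(panel.exons)
    result = DetectabilityResult(positions=[], large_indels=large)
    for (chrom, pos), vids in sorted(by_pos.items()):
        exon_ids = tuple(locator.ids_at1(chrom, pos))
        depths = np.array([depth_at(p, chrom, pos) for p in profiles], dtype=float)
        stat = float(np.mean(depths) if summary == "mean" else np.median(depths))
        summary_depth = int(np.floor(stat))
        rec = DetectabilityRecord(
            chrom=chrom,
            pos=pos,
            variant_ids=tuple(vids),
            exon_ids=exon_ids,
            captured=any(e in captured_ids for e in exon_ids),
            summary_depth=summary_depth,
            bin=bins.bin(summary_depth),
        )
        if not exon_ids:
            logger.info("%s:%d lies in no panel exon; excluded from bins", chrom, pos)
            result.excluded.append(rec)
        else:
            result.positions.append(rec)
    return result
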