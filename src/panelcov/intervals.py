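"""Panel geometry: genomic intervals, exons, gene panels and capture designs.

All interval coordinates are 0-based, half-open (BED convention).  Variant
positions, which arrive 1-based (VCF/HGMD convention), are converted exactly
once, at lookup time, by :func:`position_in_exon` and the depth accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Exon",
    "GenePanel",
    "CaptureDesign",
    "PanelFootprint",
    "ExonLocator",
    "normalize_intervals",
    "overlap_bases",
    "position_in_exon",
]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            label = f" ({self.name})" if self.name else ""
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}{label}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains0(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return chrom == self.chrom and self.start <= pos0 < self.end


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def normalize_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Sort by (chrom, start) and merge overlapping or bookended intervals.

    The union of bases is preserved exactly; an interval that survives
    un-merged keeps its name, merged runs are unnamed.  Idempotent.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
            elif prev.name and prev.name != iv.name:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, prev.end)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True, slots=True)
class Exon:
    """One panel exon: an interval tagged with its gene and a unique id."""

    interval: GenomicInterval
    gene: str
    exon_id: str


class GenePanel:
    """A curated gene list together with the exons that define its footprint.

    Exon ids must be unique and every exon's gene must be a member of the
    panel gene set.  Overlapping exons (alternate transcripts) are retained
    as distinct records; position-level statistics deduplicate by
    (chrom, pos), never by exon.
    """

    def __init__(self, genes: Iterable[str], exons: Sequence[Exon]):
        gene_list = list(genes)
        self.genes: frozenset[str] = frozenset(gene_list)
        if len(gene_list) != len(self.genes):
            dupes = sorted({g for g in gene_list if gene_list.count(g) > 1})
            raise ValueError(f"duplicate gene symbols in panel: {dupes}")
        self.exons: list[Exon] = list(exons)
        seen: set[str] = set()
        for ex in self.exons:
            if ex.exon_id in seen:
                raise ValueError(f"duplicate exon_id {ex.exon_id!r} in panel")
            seen.add(ex.exon_id)
            if ex.gene not in self.genes:
                raise ValueError(
                    f"exon {ex.exon_id!r} references gene {ex.gene!r} "
                    "absent from the panel gene list"
                )
        self._footprint: PanelFootprint | None = None
        self._by_id = {ex.exon_id: ex for ex in self.exons}

    def __len__(self) -> int:
        return len(self.exons)

    def exon(self, exon_id: str) -> Exon:
        return self._by_id[exon_id]

    @property
    def footprint(self) -> "PanelFootprint":
        """Merged union of exon intervals, built lazily and cached."""
        if self._footprint is None:
            self._footprint = PanelFootprint(
                normalize_intervals(ex.interval for ex in self.exons)
            )
        return self._footprint


def position_in_exon(
    chrom: str, pos1: int, exons: Iterable[Exon]
) -> list[str]:
    """Ids of every exon containing the 1-based position `pos1`.

    The 1-based input is converted to the exon's 0-based half-open frame,
    so pos1 == start is outside and pos1 == start + 1 is the first base.
    """
    if pos1 < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos1}")
    p0 = pos1 - 1
    return [ex.exon_id for ex in exons if ex.interval.contains0(chrom, p0)]


class CaptureDesign:
    """Normalized target intervals of a hybridization capture design.

    Construction merges overlapping/bookended targets per chromosome, so
    every base is represented at most once and overlap queries are exact.
    """

    def __init__(self, targets: Iterable[GenomicInterval]):
        self.targets: list[GenomicInterval] = normalize_intervals(targets)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in self.targets:
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        self._starts = {c: np.asarray(v, dtype=np.int64) for c, v in self._starts.items()}
        self._ends = {c: np.asarray(v, dtype=np.int64) for c, v in self._ends.items()}

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def is_empty(self) -> bool:
        return not self.targets

    def covered_bases(self, interval: GenomicInterval) -> int:
        """Bases of `interval` lying inside the target union."""
        starts = self._starts.get(interval.chrom)
        if starts is None:
            return 0
        ends = self._ends[interval.chrom]
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], interval.start)
        e = np.minimum(ends[lo:hi], interval.end)
        return int(np.maximum(e - s, 0).sum())


class PanelFootprint:
    """Flat index over the merged base set of a panel.

    Maps (chrom, 0-based position) to an offset into a single dense array,
    which is how per-sample depth vectors are stored.  Input intervals must
    already be normalized (sorted, merged).
    """

    def __init__(self, merged: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._offsets: dict[str, np.ndarray] = {}
        self._blocks: list[GenomicInterval] = list(merged)
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            per_chrom.setdefault(iv.chrom, []).append(iv)
        offset = 0
        self._chrom_order = sorted(per_chrom)
        for chrom in self._chrom_order:
            ivs = sorted(per_chrom[chrom], key=lambda x: x.start)
            self._starts[chrom] = np.asarray([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.asarray([iv.end for iv in ivs], dtype=np.int64)
            offs = []
            for iv in ivs:
                offs.append(offset)
                offset += iv.length
            self._offsets[chrom] = np.asarray(offs, dtype=np.int64)
        self.total_bases: int = offset

    def blocks(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (chrom, start, end, offset) per merged block in index order."""
        for chrom in self._chrom_order:
            for s, e, o in zip(
                self._starts[chrom], self._ends[chrom], self._offsets[chrom]
            ):
                yield chrom, int(s), int(e), int(o)

    def index(self, chrom: str, pos0: int) -> int:
        """Flat index of a 0-based position, or -1 if outside the footprint."""
        starts = self._starts.get(chrom)
        if starts is None:
            return -1
        k = int(np.searchsorted(starts, pos0, side="right")) - 1
        if k < 0 or pos0 >= self._ends[chrom][k]:
            return -1
        return int(self._offsets[chrom][k] + (pos0 - starts[k]))

    def index_array(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`index`; -1 for positions outside the footprint."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is None:
            return np.full(pos0.shape, -1, dtype=np.int64)
        k = np.searchsorted(starts, pos0, side="right") - 1
        kc = np.clip(k, 0, None)
        inside = (k >= 0) & (pos0 < self._ends[chrom][kc])
        out = self._offsets[chrom][kc] + (pos0 - starts[kc])
        return np.where(inside, out, -1)

    def contains(self, chrom: str, pos0: int) -> bool:
        return self.index(chrom, pos0) >= 0

    def range_for(self, interval: GenomicInterval) -> tuple[int, int]:
        """Contiguous flat-index slice [lo, hi) covering `interval`.

        Valid because any exon is a subset of exactly one merged block; a
        request outside the footprint is a programming error and raises.
        """
        lo = self.index(interval.chrom, interval.start)
        if lo < 0:
            raise KeyError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                "is not inside the panel footprint"
            )
        hi_last = self.index(interval.chrom, interval.end - 1)
        hi = hi_last + 1
        if hi_last < 0 or hi - lo != interval.length:
            raise KeyError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                "spans a footprint gap"
            )
        return lo, hi


class ExonLocator:
    """Batch lookup of exons containing given positions.

    Exons may overlap, so a position can map to several exon ids; lookups
    scan per-chromosome coordinate arrays vectorized with numpy.
    """

    def __init__(self, exons: Sequence[Exon]):
        self._ids: dict[str, list[str]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        per_chrom: dict[str, list[Exon]] = {}
        for ex in exons:
            per_chrom.setdefault(ex.interval.chrom, []).append(ex)
        for chrom, exs in per_chrom.items():
            self._ids[chrom] = [e.exon_id for e in exs]
            self._starts[chrom] = np.asarray(
                [e.interval.start for e in exs], dtype=np.int64
            )
            self._ends[chrom] = np.asarray(
                [e.interval.end for e in exs], dtype=np.int64
            )

    def ids_at0(self, chrom: str, pos0: int) -> list[str]:
        starts = self._starts.get(chrom)
        if starts is None:
            return []
        mask = (starts <= pos0) & (pos0 < self._ends[chrom])
        ids = self._ids[chrom]
        return [ids[i] for i in np.flatnonzero(mask)]

    def ids_at1(self, chrom: str, pos1: int) -> list[str]:
        if pos1 < 1:
            raise ValueError(f"1-based position must be >= 1, got {pos1}")
        return self.ids_at0(chrom, pos1 - 1)
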