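"""Per-exon capture assessment against a hybridization design.

An exon counts as captured when its overlap with the (merged) design
targets reaches ``min_overlap`` bases — any overlap by default, since a
non-captured exon is one the kit did not target at all.  Catalogued unique
variant positions are then partitioned by the capture status of the exons
containing them; a position inside both a captured and a non-captured exon
counts as captured, because one targeted context suffices for the base to
be sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import pct
from .intervals import CaptureDesign, ExonLocator, GenePanel

__all__ = ["CaptureReport", "assess_capture", "partition_positions_by_capture"]

CAPTURED = "captured"
NOT_CAPTURED = "not_captured"
OUTSIDE = "outside_exons"


@dataclass
class CaptureReport:
    """Capture flags per exon plus, optionally, the position partition."""

    min_overlap: int
    exon_captured: dict[str, bool]
    position_status: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def n_exons_total(self) -> int:
        return len(self.exon_captured)

    @property
    def n_captured(self) -> int:
        return sum(1 for v in self.exon_captured.values() if v)

    @property
    def n_not_captured(self) -> int:
        return self.n_exons_total - self.n_captured

    @property
    def pct_captured(self) -> float:
        return pct(self.n_captured, self.n_exons_total)

    @property
    def pct_not_captured(self) -> float:
        return pct(self.n_not_captured, self.n_exons_total)

    @property
    def n_positions_in_captured(self) -> int:
        return sum(1 for v in self.position_status.values() if v == CAPTURED)

    @property
    def n_positions_in_not_captured(self) -> int:
        return sum(1 for v in self.position_status.values() if v == NOT_CAPTURED)

    @property
    def n_positions_outside_exons(self) -> int:
        return sum(1 for v in self.position_status.values() if v == OUTSIDE)

    def exon_rows(self) -> list[dict]:
        return [
            {"exon_id": eid, "captured": flag}
            for eid, flag in sorted(self.exon_captured.items())
        ]


def assess_capture(
    panel: GenePanel, design: CaptureDesign, min_overlap: int = 1
) -> CaptureReport:
    """Flag every panel exon captured/not against the design.

    An empty design is valid (nothing is captured); an empty panel is an
    error because every downstream percentage would be undefined.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not panel.exons:
        raise ValueError("cannot assess capture of an empty panel")
    flags = {
        ex.exon_id: design.covered_bases(ex.interval) >= min_overlap
        for ex in panel.exons
    }
    return CaptureReport(min_overlap=min_overlap, exon_captured=flags)


def partition_positions_by_capture(
    positions: Iterable[tuple[str, int]],
    panel: GenePanel,
    report: CaptureReport,
) -> CaptureReport:
    """Assign each unique (chrom, 1-based pos) a capture status.

    captured — lies in >= 1 captured exon; not_captured — lies only in
    non-captured exons; outside_exons — in no panel exon (reported
    separately, excluded from both counts).  Input is deduplicated.
    The report is updated in place and returned.
    """
    locator = ExonLocator(panel.exons)
    status: dict[tuple[str, int], str] = {}
    for chrom, pos in sorted(set(positions)):
        exon_ids = locator.ids_at1(chrom, pos)
        if not exon_ids:
            status[(chrom, pos)] = OUTSIDE
        elif any(report.exon_captured[eid] for eid in exon_ids):
            status[(chrom, pos)] = CAPTURED
        else:
            status[(chrom, pos)] = NOT_CAPTURED
    report.position_status = status
    return report
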