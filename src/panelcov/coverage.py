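"""Five-tier per-exon coverage classification at a depth threshold.

An exon's covered fraction f is the share of its bases sequenced at depth
>= D (default 20 reads, inclusive).  The tiers partition [0, 1]:

    FULL    f = 1.0 (exact integer condition: every base at threshold)
    WELL    0.90 <= f < 1.0
    MOSTLY  0.70 <= f < 0.90
    LIGHT   0.40 <= f < 0.70
    NONE    f < 0.40 ("no coverage")

FULL is decided by integer comparison (n_at == n_bases), never by a float
threshold, so a 10 000-base exon with one uncovered base is WELL, not FULL.
Per-sample tier proportions are averaged unweighted across samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import Exon, ExonLocator, GenePanel
from .io import DepthProfile

__all__ = [
    "CoverageCategory",
    "CATEGORY_ORDER",
    "CoverageCategoryScheme",
    "ExonCoverageStat",
    "exon_coverage",
    "sample_exon_stats",
    "sample_category_proportions",
    "average_proportions",
    "mean_exon_fraction",
    "mean_exon_fractions",
    "positions_in_none_exons",
    "CoverageSummary",
    "summarize_coverage",
]


class CoverageCategory(enum.IntEnum):
    """Coverage tiers, ordered so that higher value = better covered."""

    NONE = 0
    LIGHT = 1
    MOSTLY = 2
    WELL = 3
    FULL = 4


# canonical report order, best tier first
CATEGORY_ORDER: list[CoverageCategory] = [
    CoverageCategory.FULL,
    CoverageCategory.WELL,
    CoverageCategory.MOSTLY,
    CoverageCategory.LIGHT,
    CoverageCategory.NONE,
]


@dataclass(frozen=True)
class CoverageCategoryScheme:
    """Depth threshold plus the fixed fraction boundaries above."""

    depth_threshold: int = 20

    def __post_init__(self) -> None:
        if self.depth_threshold < 1:
            raise ValueError("depth_threshold must be >= 1")

    def classify_counts(self, n_at_threshold: int, n_bases: int) -> CoverageCategory:
        if not 0 <= n_at_threshold <= n_bases:
            raise ValueError("need 0 <= n_at_threshold <= n_bases")
        if n_at_threshold == n_bases:
            return CoverageCategory.FULL
        f = n_at_threshold / n_bases
        if f >= 0.90:
            return CoverageCategory.WELL
        if f >= 0.70:
            return CoverageCategory.MOSTLY
        if f >= 0.40:
            return CoverageCategory.LIGHT
        return CoverageCategory.NONE


@dataclass(frozen=True)
class ExonCoverageStat:
    sample_id: str
    exon_id: str
    n_bases: int
    n_bases_at_threshold: int
    category: CoverageCategory

    @property
    def covered_fraction(self) -> float:
        return self.n_bases_at_threshold / self.n_bases


def exon_coverage(
    exon: Exon, profile: DepthProfile, scheme: CoverageCategoryScheme
) -> ExonCoverageStat:
    """Covered fraction and tier of one exon in one sample.

    Bases absent from the depth table count as depth 0, so an exon with no
    recorded depth is NONE with f = 0.
    """
    lo, hi = profile.footprint.range_for(exon.interval)
    n_at = int((profile.depth[lo:hi] >= scheme.depth_threshold).sum())
    n = exon.interval.length
    return ExonCoverageStat(
        sample_id=profile.sample_id,
        exon_id=exon.exon_id,
        n_bases=n,
        n_bases_at_threshold=n_at,
        category=scheme.classify_counts(n_at, n),
    )


def sample_exon_stats(
    panel: GenePanel,
    profile: DepthProfile,
    scheme: CoverageCategoryScheme,
    exon_ids: Iterable[str] | None = None,
) -> list[ExonCoverageStat]:
    """All per-exon stats for one sample, vectorized over the footprint.

    `exon_ids` restricts the computation (e.g. to captured exons only).
    """
    at = (profile.depth >= scheme.depth_threshold).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(at)))
    wanted = set(exon_ids) if exon_ids is not None else None
    stats: list[ExonCoverageStat] = []
    for ex in panel.exons:
        if wanted is not None and ex.exon_id not in wanted:
            continue
        lo, hi = profile.footprint.range_for(ex.interval)
        n_at = int(cum[hi] - cum[lo])
        n = ex.interval.length
        stats.append(
            ExonCoverageStat(
                sample_id=profile.sample_id,
                exon_id=ex.exon_id,
                n_bases=n,
                n_bases_at_threshold=n_at,
                category=scheme.classify_counts(n_at, n),
            )
        )
    return stats


def sample_category_proportions(stats: Sequence[ExonCoverageStat]) -> np.ndarray:
    """Tier proportions for one sample, in CATEGORY_ORDER; sums to 1."""
    if not stats:
        raise ValueError("cannot compute proportions of an empty stat list")
    counts = np.zeros(len(CATEGORY_ORDER))
    index = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    for s in stats:
        counts[index[s.category]] += 1
    return counts / counts.sum()


def average_proportions(per_sample: Sequence[np.ndarray]) -> np.ndarray:
    """Unweighted arithmetic mean of per-sample tier proportions."""
    if not len(per_sample):
        raise ValueError("need at least one sample")
    return np.mean(np.asarray(per_sample, dtype=float), axis=0)


def mean_exon_fraction(
    exon_id: str, per_sample_stats: Mapping[str, Sequence[ExonCoverageStat]]
) -> float:
    """Mean covered fraction of one exon across samples.

    Every sample must report the exon; a sample missing it is named in the
    error rather than silently skipped.
    """
    fractions = []
    for sample_id, stats in per_sample_stats.items():
        hit = [s for s in stats if s.exon_id == exon_id]
        if not hit:
            raise ValueError(f"sample {sample_id!r} has no stat for exon {exon_id!r}")
        fractions.append(hit[0].covered_fraction)
    if not fractions:
        raise ValueError("no samples given")
    return float(np.mean(fractions))


def mean_exon_fractions(
    per_sample_stats: Mapping[str, Sequence[ExonCoverageStat]],
) -> dict[str, float]:
    """Per-exon mean covered fraction across samples (all exons at once)."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_samples = len(per_sample_stats)
    for sample_id, stats in per_sample_stats.items():
        for s in stats:
            sums[s.exon_id] = sums.get(s.exon_id, 0.0) + s.covered_fraction
            counts[s.exon_id] = counts.get(s.exon_id, 0) + 1
    for exon_id, c in counts.items():
        if c != n_samples:
            raise ValueError(
                f"exon {exon_id!r} present in {c}/{n_samples} samples"
            )
    return {eid: sums[eid] / n_samples for eid in sorted(sums)}


def positions_in_none_exons(
    positions: Iterable[tuple[str, int]],
    per_sample_stats: Mapping[str, Sequence[ExonCoverageStat]],
    panel: GenePanel,
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-sample count of unique positions whose every classified exon is NONE.

    A position inside two exons of different tiers counts by the best tier
    — it enters the NONE count only if every containing exon with a stat
    is NONE in that sample.  Positions (1-based) are deduplicated; a
    position in no classified exon is not counted.  Returns the per-sample
    counts and a summary (min/max/median/mean across samples; median over
    an even sample count is the mean of the two central order statistics).
    """
    locator = ExonLocator(panel.exons)
    pos_exons = {
        (chrom, pos): locator.ids_at1(chrom, pos)
        for chrom, pos in sorted(set(positions))
    }
    counts: dict[str, int] = {}
    for sample_id, stats in per_sample_stats.items():
        cat = {s.exon_id: s.category for s in stats}
        n = 0
        for _, exon_ids in pos_exons.items():
            tiers = [cat[eid] for eid in exon_ids if eid in cat]
            if tiers and max(tiers) == CoverageCategory.NONE:
                n += 1
        counts[sample_id] = n
    values = np.array(list(counts.values()), dtype=float)
    summary = {
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
        "mean": float(values.mean()),
    }
    return counts, summary


@dataclass
class CoverageSummary:
    """Aggregated coverage classification for a cohort of samples."""

    scheme: CoverageCategoryScheme
    per_sample_stats: dict[str, list[ExonCoverageStat]]
    per_sample_proportions: dict[str, np.ndarray]
    mean_proportions: np.ndarray
    mean_fraction_by_exon: dict[str, float]
    none_position_counts: dict[str, int] | None = None
    none_position_summary: dict[str, float] | None = None

    def proportion_rows(self) -> list[dict]:
        rows = []
        for sample_id in sorted(self.per_sample_proportions):
            row: dict = {"sample_id": sample_id}
            for cat, p in zip(CATEGORY_ORDER, self.per_sample_proportions[sample_id]):
                row[f"prop_{cat.name.lower()}"] = float(p)
            rows.append(row)
        return rows

    def mean_proportion_dict(self) -> dict[str, float]:
        return {
            cat.name.lower(): float(p)
            for cat, p in zip(CATEGORY_ORDER, self.mean_proportions)
        }


def summarize_coverage(
    panel: GenePanel,
    profiles: Sequence[DepthProfile],
    scheme: CoverageCategoryScheme | None = None,
    capture_report=None,
    denominator: str = "captured-only",
    unique_positions: Iterable[tuple[str, int]] | None = None,
) -> CoverageSummary:
    """Classify every exon in every sample and aggregate across the cohort.

    `denominator` chooses whether tier proportions run over captured exons
    only (default, requires a capture report) or over all panel exons.
    When catalogued unique positions are supplied, the per-sample counts of
    positions stranded in NONE exons are computed as well.
    """
    if scheme is None:
        scheme = CoverageCategoryScheme()
    if denominator not in ("captured-only", "all-exons"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if denominator == "captured-only":
        if capture_report is None:
            raise ValueError("captured-only mode needs a capture report")
        exon_ids = sorted(
            eid for eid, flag in capture_report.exon_captured.items() if flag
        )
    else:
        exon_ids = None
    per_sample_stats = {
        p.sample_id: sample_exon_stats(panel, p, scheme, exon_ids) for p in profiles
    }
    per_sample_props = {
        sid: sample_category_proportions(stats)
        for sid, stats in per_sample_stats.items()
    }
    mean_props = average_proportions(list(per_sample_props.values()))
    mean_fracs = mean_exon_fractions(per_sample_stats)
    none_counts = none_summary = None
    if unique_positions is not None:
        none_counts, none_summary = positions_in_none_exons(
            unique_positions, per_sample_stats, panel
        )
    return CoverageSummary(
        scheme=scheme,
        per_sample_stats=per_sample_stats,
        per_sample_proportions=per_sample_props,
        mean_proportions=mean_props,
        mean_fraction_by_exon=mean_fracs,
        none_position_counts=none_counts,
        none_position_summary=none_summary,
    )
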