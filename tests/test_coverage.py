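"""Five-tier coverage classification and its aggregations."""

import numpy as np
import pytest

from panelcov.coverage import (
    CATEGORY_ORDER,
    CoverageCategory,
    CoverageCategoryScheme,
    average_proportions,
    exon_coverage,
    mean_exon_fraction,
    positions_in_none_exons,
    sample_category_proportions,
    sample_exon_stats,
)
from panelcov.intervals import Exon, GenePanel, GenomicInterval
from panelcov.io import DepthProfile


def _profile(panel, depths, sample_id="S1"):
    return DepthProfile(sample_id, panel.footprint, np.asarray(depths, dtype=np.int32))


def _one_exon_panel(length=10):
    ex = Exon(GenomicInterval("chr1", 0, length), "G", "e1")
    return GenePanel(["G"], [ex]), ex


class TestClassification:
    @pytest.mark.parametrize(
        "n_at,n,expected",
        [
            (10, 10, CoverageCategory.FULL),
            (9, 10, CoverageCategory.WELL),  # 0.90 boundary is inclusive
            (9999, 10000, CoverageCategory.WELL),  # not FULL: integer condition
            (89, 100, CoverageCategory.MOSTLY),
            (70, 100, CoverageCategory.MOSTLY),
            (69, 100, CoverageCategory.LIGHT),
            (40, 100, CoverageCategory.LIGHT),
            (39, 100, CoverageCategory.NONE),
            (0, 10, CoverageCategory.NONE),
        ],
    )
    def test_boundaries(self, n_at, n, expected):
        assert CoverageCategoryScheme().classify_counts(n_at, n) is expected

    def test_every_fraction_maps_to_exactly_one_tier(self):
        scheme = CoverageCategoryScheme()
        for n in (7, 10, 33, 100):
            for n_at in range(n + 1):
                scheme.classify_counts(n_at, n)  # raises if unclassifiable

    def test_depth_threshold_inclusive(self):
        panel, ex = _one_exon_panel(10)
        stat = exon_coverage(ex, _profile(panel, [20] * 10), CoverageCategoryScheme(20))
        assert stat.covered_fraction == 1.0
        assert stat.category is CoverageCategory.FULL

    def test_nine_of_ten_bases_is_well(self):
        panel, ex = _one_exon_panel(10)
        stat = exon_coverage(
            ex, _profile(panel, [25] * 9 + [0]), CoverageCategoryScheme(20)
        )
        assert stat.covered_fraction == pytest.approx(0.9)
        assert stat.category is CoverageCategory.WELL

    def test_all_zero_depth_exon_is_none(self):
        panel, ex = _one_exon_panel(10)
        stat = exon_coverage(ex, _profile(panel, [0] * 10), CoverageCategoryScheme())
        assert stat.covered_fraction == 0.0
        assert stat.category is CoverageCategory.NONE

    def test_fraction_matches_per_base_oracle(self):
        rng = np.random.default_rng(21)
        exons, depths = [], []
        pos = 0
        for k in range(200):
            L = int(rng.integers(5, 60))
            exons.append(Exon(GenomicInterval("chr1", pos, pos + L), "G", f"e{k}"))
            pos += L + int(rng.integers(1, 30))
        panel = GenePanel(["G"], exons)
        depth = rng.integers(0, 50, size=panel.footprint.total_bases).astype(np.int32)
        profile = DepthProfile("S1", panel.footprint, depth)
        scheme = CoverageCategoryScheme(20)
        stats = {s.exon_id: s for s in sample_exon_stats(panel, profile, scheme)}
        for ex in exons:
            oracle = sum(
                profile.get("chr1", p) >= 20
                for p in range(ex.interval.start, ex.interval.end)
            )
            assert stats[ex.exon_id].n_bases_at_threshold == oracle

    def test_raising_threshold_never_raises_fraction_or_tier(self):
        rng = np.random.default_rng(22)
        panel, ex = _one_exon_panel(50)
        profile = _profile(panel, rng.integers(0, 60, size=50))
        prev_f, prev_cat = 2.0, CoverageCategory.FULL
        for D in (5, 10, 20, 30, 50):
            stat = exon_coverage(ex, profile, CoverageCategoryScheme(D))
            assert stat.covered_fraction <= prev_f
            assert stat.category <= prev_cat
            prev_f, prev_cat = stat.covered_fraction, stat.category


class TestAggregation:
    def _stats(self, categories, sample_id="S1"):
        return [
            # counts chosen so each category is self-consistent
            _stat_for(cat, i, sample_id) for i, cat in enumerate(categories)
        ]

    def test_all_full_is_degenerate_distribution(self):
        props = sample_category_proportions(self._stats([CoverageCategory.FULL] * 4))
        assert props.tolist() == [1, 0, 0, 0, 0]

    def test_direct_ratio(self):
        cats = (
            [CoverageCategory.FULL] * 81
            + [CoverageCategory.WELL] * 5
            + [CoverageCategory.MOSTLY] * 5
            + [CoverageCategory.LIGHT] * 3
            + [CoverageCategory.NONE] * 6
        )
        props = sample_category_proportions(self._stats(cats))
        assert props.tolist() == pytest.approx([0.81, 0.05, 0.05, 0.03, 0.06])
        assert props.sum() == pytest.approx(1.0, abs=1e-9)

    def test_random_categories_match_tally_oracle(self):
        rng = np.random.default_rng(23)
        cats = [CATEGORY_ORDER[i] for i in rng.integers(0, 5, size=137)]
        props = sample_category_proportions(self._stats(cats))
        for cat, p in zip(CATEGORY_ORDER, props):
            assert p == pytest.approx(cats.count(cat) / 137)

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError):
            sample_category_proportions([])

    def test_average_is_identity_for_one_sample_and_mean_for_two(self):
        a = np.array([1.0, 0, 0, 0, 0])
        b = np.array([0, 1.0, 0, 0, 0])
        assert average_proportions([a]).tolist() == a.tolist()
        assert average_proportions([a, b]).tolist() == [0.5, 0.5, 0, 0, 0]

    def test_mean_exon_fraction(self):
        per_sample = {
            "S1": [_frac_stat("e1", 0.0, "S1")],
            "S2": [_frac_stat("e1", 1.0, "S2")],
        }
        assert mean_exon_fraction("e1", per_sample) == pytest.approx(0.5)

    def test_mean_exon_fraction_names_missing_sample(self):
        per_sample = {"S1": [_frac_stat("e1", 0.5, "S1")], "S2": []}
        with pytest.raises(ValueError, match="S2"):
            mean_exon_fraction("e1", per_sample)


class TestPositionsInNoneExons:
    def _panel(self):
        exons = [
            Exon(GenomicInterval("chr1", 0, 10), "G", "e1"),
            Exon(GenomicInterval("chr1", 5, 15), "G", "e2"),  # overlaps e1
            Exon(GenomicInterval("chr1", 100, 110), "G", "e3"),
        ]
        return GenePanel(["G"], exons)

    def test_counts_and_best_category_rule(self):
        panel = self._panel()
        stats = {
            "S1": [
                _stat_as("e1", CoverageCategory.NONE, "S1"),
                _stat_as("e2", CoverageCategory.FULL, "S1"),
                _stat_as("e3", CoverageCategory.NONE, "S1"),
            ],
            "S2": [
                _stat_as("e1", CoverageCategory.FULL, "S2"),
                _stat_as("e2", CoverageCategory.FULL, "S2"),
                _stat_as("e3", CoverageCategory.FULL, "S2"),
            ],
        }
        # pos 3 only in e1 (NONE in S1); pos 7 in e1+e2 (best is FULL);
        # pos 101..103 in e3 (NONE in S1); dedup means 3 counted once
        positions = [("chr1", 3), ("chr1", 7), ("chr1", 101), ("chr1", 102),
                     ("chr1", 103), ("chr1", 103)]
        counts, summary = positions_in_none_exons(positions, stats, panel)
        assert counts == {"S1": 4, "S2": 0}
        assert summary == {"min": 0.0, "max": 4.0, "median": 2.0, "mean": 2.0}

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(29)
        panel = self._panel()
        per_sample = {}
        for s in range(5):
            per_sample[f"S{s}"] = [
                _stat_as(eid, CATEGORY_ORDER[int(rng.integers(0, 5))], f"S{s}")
                for eid in ("e1", "e2", "e3")
            ]
        positions = {("chr1", int(rng.integers(1, 120))) for _ in range(60)}
        counts, _ = positions_in_none_exons(positions, per_sample, panel)
        for sid, stats in per_sample.items():
            cat = {st.exon_id: st.category for st in stats}
            expected = 0
            for chrom, pos1 in positions:
                tiers = [
                    cat[ex.exon_id]
                    for ex in panel.exons
                    if ex.interval.chrom == chrom
                    and ex.interval.start <= pos1 - 1 < ex.interval.end
                ]
                if tiers and all(t is CoverageCategory.NONE for t in tiers):
                    expected += 1
            assert counts[sid] == expected


# -- helpers ---------------------------------------------------------------

_COUNTS = {
    CoverageCategory.FULL: (10, 10),
    CoverageCategory.WELL: (9, 10),
    CoverageCategory.MOSTLY: (8, 10),
    CoverageCategory.LIGHT: (5, 10),
    CoverageCategory.NONE: (0, 10),
}


def _stat_for(cat, i, sample_id):
    from panelcov.coverage import ExonCoverageStat

    n_at, n = _COUNTS[cat]
    return ExonCoverageStat(sample_id, f"x{i}", n, n_at, cat)


def _stat_as(exon_id, cat, sample_id):
    from panelcov.coverage import ExonCoverageStat

    n_at, n = _COUNTS[cat]
    return ExonCoverageStat(sample_id, exon_id, n, n_at, cat)


def _frac_stat(exon_id, frac, sample_id):
    from panelcov.coverage import ExonCoverageStat

    n = 10
    n_at = int(round(frac * n))
    return ExonCoverageStat(
        sample_id, exon_id, n, n_at, CoverageCategoryScheme().classify_counts(n_at, n)
    )
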