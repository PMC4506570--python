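"""Catalogue partition and per-position depth binning."""

import numpy as np
import pytest

from panelcov.intervals import CaptureDesign, Exon, GenePanel, GenomicInterval
from panelcov.io import DepthProfile
from panelcov.variants import (
    BIN_ORDER,
    DepthBin,
    DetectabilityBins,
    VariantClass,
    VariantRecord,
    depth_at,
    detectability,
    partition_catalogue,
    unique_positions,
)


def pv(vid, chrom, pos, alt="T", gene="G", patho="pathogenic"):
    return VariantRecord(vid, gene, VariantClass.POSITIONAL, chrom, pos,
                         "A", alt, f"c.{pos}A>{alt}", patho)


def li(vid, gene="G"):
    return VariantRecord(vid, gene, VariantClass.LARGE_INDEL,
                         hgvs_c="c.1_9del", pathogenicity="pathogenic")


class TestVariantRecord:
    def test_positional_requires_coordinates(self):
        with pytest.raises(ValueError, match="lacks chrom/pos"):
            VariantRecord("v", "G", VariantClass.POSITIONAL)

    def test_large_indel_must_be_coordinate_free(self):
        with pytest.raises(ValueError, match="must not"):
            VariantRecord("v", "G", VariantClass.LARGE_INDEL, "chr1", 5)

    def test_unknown_pathogenicity_rejected(self):
        with pytest.raises(ValueError, match="pathogenicity"):
            pv("v", "chr1", 5, patho="benign-ish")


class TestPartition:
    def test_smallest_multiallelic_case(self):
        records = [pv("v1", "chr1", 5, "T"), pv("v2", "chr1", 5, "G"),
                   pv("v3", "chr1", 9)]
        part = partition_catalogue(records)
        assert part.n_unique_positions == 2
        assert part.n_multiallelic_positions == 1
        assert part.n_positional == 3 and part.n_large_indel == 0

    def test_classes_conserve_total(self):
        records = [pv("v1", "chr1", 5), li("v2"), li("v3")]
        part = partition_catalogue(records)
        assert part.n_large_indel + part.n_positional == part.n_total == 3

    def test_order_invariance_and_grouping_oracle(self):
        rng = np.random.default_rng(31)
        records = []
        for k in range(400):
            chrom = f"chr{rng.integers(1, 3)}"
            pos = int(rng.integers(1, 120))
            records.append(pv(f"v{k}", chrom, pos, alt="ACGT"[rng.integers(4)]))
        for k in range(80):
            records.append(li(f"w{k}"))
        part = partition_catalogue(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert partition_catalogue(shuffled) == part
        # independent hash-grouping oracle
        groups = {}
        for r in records:
            if r.variant_class is VariantClass.POSITIONAL:
                groups.setdefault((r.chrom, r.pos), []).append(r)
        assert part.n_unique_positions == len(groups)
        assert part.n_multiallelic_positions == sum(
            1 for g in groups.values() if len(g) >= 2
        )
        assert unique_positions(records) == sorted(groups)


class TestBins:
    @pytest.mark.parametrize(
        "depth,expected",
        [
            (20, DepthBin.ADEQUATE),  # inclusive threshold
            (100, DepthBin.ADEQUATE),
            (19, DepthBin.MID),
            (10, DepthBin.MID),
            (9, DepthBin.LOW),
            (5, DepthBin.LOW),
            (4, DepthBin.VERY_LOW),
            (0, DepthBin.VERY_LOW),
        ],
    )
    def test_edges(self, depth, expected):
        assert DetectabilityBins(20).bin(depth) is expected

    def test_bins_partition_nonnegative_integers(self):
        bins = DetectabilityBins(25)
        for d in range(0, 60):
            bins.bin(d)  # exactly one bin, raises otherwise

    def test_threshold_at_or_below_fixed_edge_rejected(self):
        with pytest.raises(ValueError):
            DetectabilityBins(10)


class TestDepthAt:
    def test_lookup_and_absent_default(self, tiny_panel):
        fp = tiny_panel.footprint
        depth = np.zeros(fp.total_bases, dtype=np.int32)
        depth[fp.index("chr1", 10)] = 25
        prof = DepthProfile("S1", fp, depth)
        assert depth_at(prof, "chr1", 11) == 25  # 1-based
        assert depth_at(prof, "chr1", 12) == 0
        assert depth_at(prof, "chr9", 5) == 0  # outside footprint


class TestDetectability:
    def _fixture(self, depths_by_pos, n_samples=3):
        """One 100-base exon; every sample has the same per-base depth."""
        ex = Exon(GenomicInterval("chr1", 0, 100), "G", "e1")
        panel = GenePanel(["G"], [ex])
        design = CaptureDesign([GenomicInterval("chr1", 0, 100)])
        fp = panel.footprint
        depth = np.zeros(fp.total_bases, dtype=np.int32)
        for pos1, d in depths_by_pos.items():
            depth[fp.index("chr1", pos1 - 1)] = d
        profiles = [DepthProfile(f"S{i}", fp, depth.copy()) for i in range(n_samples)]
        return panel, design, profiles

    def test_low_depth_variants_fall_in_expected_bins(self):
        depths = {1: 12, 2: 2, 3: 11, 4: 1, 5: 13}
        panel, design, profiles = self._fixture(depths)
        records = [pv(f"v{p}", "chr1", p) for p in depths]
        res = detectability(records, profiles, panel, design=design)
        assert res.bin_counts[DepthBin.MID] == 3  # depths 12, 11, 13
        assert res.bin_counts[DepthBin.VERY_LOW] == 2  # depths 2, 1
        assert res.bin_counts[DepthBin.ADEQUATE] == 0
        assert sum(res.bin_counts.values()) == len(res.positions) == 5

    def test_multiallelic_position_shares_one_record(self):
        panel, design, profiles = self._fixture({7: 30})
        records = [pv("v1", "chr1", 7, "T"), pv("v2", "chr1", 7, "G")]
        res = detectability(records, profiles, panel, design=design)
        assert len(res.positions) == 1
        assert res.positions[0].variant_ids == ("v1", "v2")
        assert len(res.per_variant_rows()) == 2  # per-record rows still emitted

    def test_large_indels_never_binned(self):
        panel, design, profiles = self._fixture({7: 30})
        res = detectability([li("w1"), pv("v1", "chr1", 7)], profiles, panel,
                            design=design)
        assert [r.variant_id for r in res.large_indels] == ["w1"]
        assert sum(res.bin_counts.values()) == 1

    def test_variant_outside_panel_excluded_from_bins(self):
        panel, design, profiles = self._fixture({7: 30})
        res = detectability([pv("v1", "chr1", 7), pv("v2", "chr2", 500)],
                            profiles, panel, design=design)
        assert len(res.positions) == 1
        assert [r.pos for r in res.excluded] == [500]

    def test_summary_depth_is_floored_mean_and_median_available(self):
        ex = Exon(GenomicInterval("chr1", 0, 10), "G", "e1")
        panel = GenePanel(["G"], [ex])
        design = CaptureDesign([GenomicInterval("chr1", 0, 10)])
        fp = panel.footprint
        profiles = []
        for i, d in enumerate([10, 11, 30]):  # mean 17, median 11
            depth = np.zeros(fp.total_bases, dtype=np.int32)
            depth[fp.index("chr1", 4)] = d
            profiles.append(DepthProfile(f"S{i}", fp, depth))
        rec = pv("v1", "chr1", 5)
        res_mean = detectability([rec], profiles, panel, design=design)
        assert res_mean.positions[0].summary_depth == 17
        res_med = detectability([rec], profiles, panel, design=design,
                                summary="median")
        assert res_med.positions[0].summary_depth == 11

    def test_bin_tallies_match_comparison_loop_oracle(self):
        rng = np.random.default_rng(37)
        depths = {int(p): int(rng.integers(0, 60))
                  for p in rng.choice(np.arange(1, 101), 50, replace=False)}
        panel, design, profiles = self._fixture(depths, n_samples=1)
        records = [pv(f"v{p}", "chr1", p) for p in depths]
        for D in (12, 20, 35):
            bins = DetectabilityBins(D)
            res = detectability(records, profiles, panel, design=design, bins=bins)
            oracle = {b: 0 for b in BIN_ORDER}
            for d in depths.values():
                if d >= D:
                    oracle[DepthBin.ADEQUATE] += 1
                elif d >= 10:
                    oracle[DepthBin.MID] += 1
                elif d >= 5:
                    oracle[DepthBin.LOW] += 1
                else:
                    oracle[DepthBin.VERY_LOW] += 1
            assert res.bin_counts == oracle

    def test_raising_threshold_only_drains_adequate(self):
        rng = np.random.default_rng(41)
        depths = {int(p): int(rng.integers(0, 60))
                  for p in rng.choice(np.arange(1, 101), 40, replace=False)}
        panel, design, profiles = self._fixture(depths, n_samples=1)
        records = [pv(f"v{p}", "chr1", p) for p in depths]
        prev = None
        for D in (12, 20, 30, 50):
            counts = detectability(records, profiles, panel, design=design,
                                   bins=DetectabilityBins(D)).bin_counts
            if prev is not None:
                assert counts[DepthBin.ADEQUATE] <= prev[DepthBin.ADEQUATE]
                assert counts[DepthBin.MID] >= prev[DepthBin.MID]
                # the fixed 5x/10x strata are unaffected by the threshold
                assert counts[DepthBin.LOW] == prev[DepthBin.LOW]
                assert counts[DepthBin.VERY_LOW] == prev[DepthBin.VERY_LOW]
            prev = counts
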