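"""Synthetic panels, capture designs, depth profiles, catalogues, findings.

Every generator plants known structure and emits machine-readable ground
truth, so each analysis stage can be verified round-trip without external
data.  Defaults emulate the scale and rates of a 103-gene sudden-cardiac-
arrest/death exome study: ~2,190 exons, 2.4 % capture dropout, 72 samples,
a tier mixture dominated by fully covered exons, and an 11,452-record
catalogue of which 16.6 % are coordinate-free large indels.

Two depth modes:

* ``exact`` — each (sample, exon) is assigned a coverage tier by exact
  quota over the configured mixture and exactly the right number of bases
  is placed at/above the depth threshold, so the classifier must recover
  the planted tiers and per-sample tier proportions identically;
* ``stochastic`` — tiers are drawn i.i.d. from the mixture (per-sample
  proportions then fluctuate multinomially around it) and per-base depths
  are drawn from negative-binomial-shaped noise constrained to the planted
  tier's fraction band.

Synthetic chromosomes are named ``chrS1`` …; no real-genome coordinates
are imitated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .capture import assess_capture
from .coverage import CATEGORY_ORDER, CoverageCategory
from .intervals import CaptureDesign, Exon, GenePanel, GenomicInterval
from .io import (
    DepthProfile,
    load_sca_d_genes,
    write_bed,
    write_depth_bed,
    write_variant_catalogue,
)
from .triage import CaseFinding, write_findings
from .variants import CataloguePartition, VariantClass, VariantRecord

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "gen_panel",
    "gen_capture",
    "gen_depth",
    "gen_variants",
    "gen_findings",
    "simulate",
]

# fraction bands per tier, matching the classifier boundaries
_BANDS = {
    CoverageCategory.FULL: (1.0, 1.0),
    CoverageCategory.WELL: (0.90, 1.0),
    CoverageCategory.MOSTLY: (0.70, 0.90),
    CoverageCategory.LIGHT: (0.40, 0.70),
    CoverageCategory.NONE: (0.0, 0.40),
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 0
    # panel geometry
    n_genes: int = 103
    n_exons_total: int | None = 2190  # exact total; None = draw per gene
    exons_per_gene: tuple[int, int] = (4, 40)  # inclusive range
    exon_length: tuple[int, int] = (50, 300)  # inclusive range, >= 20
    exon_gap: tuple[int, int] = (100, 5000)
    # capture design
    p_not_captured: float = 0.024
    n_not_captured: int | None = None  # exact dropout count overrides p
    target_edge_trim: int = 0
    # depth model
    n_samples: int = 72
    depth_threshold: int = 20
    depth_mode: str = "exact"  # exact | stochastic
    category_mixture: tuple[float, ...] = (0.81, 0.0504, 0.0491, 0.0339, 0.0566)
    covered_depth_mean: float = 100.0  # study sequenced at ~100x average
    covered_depth_dispersion: float = 3.0  # NB size parameter
    uncovered_depth_mean: float = 4.0
    # variant catalogue
    n_variants_total: int = 11452
    frac_large_indel: float = 1896 / 11452
    frac_multiallelic: float = 978 / 8578
    n_positions_in_noncaptured: int | None = None  # None = uniform placement
    pathogenicity_mixture: tuple[float, ...] = (0.55, 0.15, 0.25, 0.05)
    # diagnostic cohorts
    n_cases_unknown: int = 30
    planted_verdicts: tuple[int, int, int] = (5, 16, 9)  # positive/uncertain/negative
    n_cases_known: int = 13

    def __post_init__(self) -> None:
        if abs(sum(self.category_mixture) - 1.0) > 1e-9:
            raise ValueError("category_mixture must sum to 1")
        if len(self.category_mixture) != 5:
            raise ValueError("category_mixture needs 5 tiers")
        if abs(sum(self.pathogenicity_mixture) - 1.0) > 1e-9:
            raise ValueError("pathogenicity_mixture must sum to 1")
        if not 0 <= self.p_not_captured < 1:
            raise ValueError("p_not_captured must be in [0, 1)")
        if self.exon_length[0] < 20:
            raise ValueError("exon length must be >= 20 bases")
        if self.depth_mode not in ("exact", "stochastic"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")
        if sum(self.planted_verdicts) != self.n_cases_unknown:
            raise ValueError("planted_verdicts must sum to n_cases_unknown")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "exons_per_gene",
            "exon_length",
            "exon_gap",
            "category_mixture",
            "pathogenicity_mixture",
            "planted_verdicts",
        ):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for k, v in raw.items():
            if isinstance(v, tuple):
                raw[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SimulatedDataset:
    """Everything one seeded simulation produced, plus its ground truth."""

    config: SimulationConfig
    panel: GenePanel
    design: CaptureDesign
    dropped_exon_ids: list[str]
    profiles: list[DepthProfile]
    planted_categories: dict[str, dict[str, str]]  # sample -> exon -> tier name
    variants: list[VariantRecord]
    planted_partition: CataloguePartition
    planted_positions_in_noncaptured: int
    findings_unknown: list[CaseFinding]
    findings_known: list[CaseFinding]
    planted_verdicts: dict[str, str]

    def ground_truth(self) -> dict:
        return {
            "dropped_exon_ids": sorted(self.dropped_exon_ids),
            "planted_categories": {
                s: dict(sorted(m.items()))
                for s, m in sorted(self.planted_categories.items())
            },
            "catalogue_partition": {
                "n_total": self.planted_partition.n_total,
                "n_large_indel": self.planted_partition.n_large_indel,
                "n_positional": self.planted_partition.n_positional,
                "n_unique_positions": self.planted_partition.n_unique_positions,
                "n_multiallelic_positions": self.planted_partition.n_multiallelic_positions,
            },
            "n_positions_in_noncaptured": self.planted_positions_in_noncaptured,
            "planted_verdicts": dict(sorted(self.planted_verdicts.items())),
            "category_mixture": list(self.config.category_mixture),
        }


# ---------------------------------------------------------------------------


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_panel(config: SimulationConfig, rng: np.random.Generator) -> GenePanel:
    """One synthetic chromosome per gene, non-overlapping exons, exact
    total exon count when `n_exons_total` is set."""
    genes = load_sca_d_genes()
    if config.n_genes > len(genes):
        genes = genes + [f"GENE{i:03d}" for i in range(config.n_genes - len(genes))]
    genes = genes[: config.n_genes]
    lo, hi = config.exons_per_gene
    counts = rng.integers(lo, hi + 1, size=config.n_genes)
    if config.n_exons_total is not None:
        # repair the draw to hit the requested total without leaving the range
        diff = config.n_exons_total - int(counts.sum())
        step = 1 if diff > 0 else -1
        bound = hi if diff > 0 else lo
        while diff != 0:
            candidates = np.flatnonzero(counts != bound)
            if not candidates.size:
                raise ValueError(
                    "n_exons_total infeasible for the exons_per_gene range"
                )
            i = rng.choice(candidates)
            counts[i] += step
            diff -= step
    exons: list[Exon] = []
    for g, gene in enumerate(genes):
        chrom = f"chrS{g + 1}"
        pos = int(rng.integers(*config.exon_gap))
        for k in range(int(counts[g])):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            iv = GenomicInterval(chrom, pos, pos + length)
            exons.append(Exon(iv, gene, f"{gene}_e{k + 1}"))
            pos += length + int(rng.integers(*config.exon_gap))
    return GenePanel(genes, exons)


def gen_capture(
    panel: GenePanel, config: SimulationConfig, rng: np.random.Generator
) -> tuple[CaptureDesign, list[str]]:
    """Drop exons from the design (Bernoulli p, or an exact count), trim
    target edges; returns the design and the dropped exon ids (ground
    truth)."""
    n = len(panel.exons)
    if config.n_not_captured is not None:
        dropped_idx = set(
            rng.choice(n, size=config.n_not_captured, replace=False).tolist()
        )
    else:
        dropped_idx = set(
            np.flatnonzero(rng.random(n) < config.p_not_captured).tolist()
        )
    targets: list[GenomicInterval] = []
    dropped: list[str] = []
    trim = config.target_edge_trim
    for i, ex in enumerate(panel.exons):
        if i in dropped_idx:
            dropped.append(ex.exon_id)
            continue
        iv = ex.interval
        s, e = iv.start, iv.end
        if trim and e - s > 2 * trim:
            s, e = s + trim, e - trim
        targets.append(GenomicInterval(iv.chrom, s, e))
    return CaptureDesign(targets), dropped


def _tier_count_range(category: CoverageCategory, length: int) -> tuple[int, int]:
    """Inclusive range of at-threshold base counts whose fraction lands in
    the tier's band.  Non-empty for every tier once length >= 20."""
    if category is CoverageCategory.FULL:
        return length, length
    lo_f, hi_f = _BANDS[category]
    lo = int(np.ceil(lo_f * length))
    hi = int(np.ceil(hi_f * length)) - 1
    return lo, hi


def _exact_quota(mixture: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of n exons over the tier mixture."""
    raw = np.asarray(mixture) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def gen_depth(
    panel: GenePanel,
    design: CaptureDesign,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[DepthProfile], dict[str, dict[str, str]]]:
    """Per-sample depth profiles with planted per-exon coverage tiers.

    Captured exons get a tier (exact quota or i.i.d. draw depending on
    mode) and exactly a tier-consistent number of bases at/above the
    threshold; non-captured exons get depth 0 throughout and no planted
    tier.  Returns profiles plus sample -> exon_id -> tier name.
    """
    D = config.depth_threshold
    footprint = panel.footprint
    captured_flags = assess_capture(panel, design).exon_captured
    captured_exons = [ex for ex in panel.exons if captured_flags[ex.exon_id]]
    ranges = {ex.exon_id: footprint.range_for(ex.interval) for ex in panel.exons}

    profiles: list[DepthProfile] = []
    planted: dict[str, dict[str, str]] = {}
    n_cap = len(captured_exons)
    quota = _exact_quota(config.category_mixture, n_cap)
    for s in range(config.n_samples):
        sample_id = f"S{s + 1:03d}"
        depth = np.zeros(footprint.total_bases, dtype=np.int32)
        if config.depth_mode == "exact":
            tiers = np.repeat(np.arange(5), quota)
            rng.shuffle(tiers)
        else:
            tiers = rng.choice(5, size=n_cap, p=config.category_mixture)
        tier_of: dict[str, str] = {}
        for ex, t in zip(captured_exons, tiers):
            cat = CATEGORY_ORDER[int(t)]
            tier_of[ex.exon_id] = cat.name
            lo, hi = ranges[ex.exon_id]
            L = hi - lo
            c_lo, c_hi = _tier_count_range(cat, L)
            n_at = int(rng.integers(c_lo, c_hi + 1)) if c_hi > c_lo else c_lo
            seg = np.empty(L, dtype=np.int32)
            if config.depth_mode == "exact":
                covered_draw = D + rng.integers(0, 81, size=n_at)
                uncovered_draw = rng.integers(0, D, size=L - n_at)
            else:
                p_cov = config.covered_depth_dispersion / (
                    config.covered_depth_dispersion + max(config.covered_depth_mean - D, 1.0)
                )
                covered_draw = D + rng.negative_binomial(
                    config.covered_depth_dispersion, p_cov, size=n_at
                )
                p_unc = 1.0 / (1.0 + config.uncovered_depth_mean)
                uncovered_draw = np.minimum(
                    rng.negative_binomial(1.0, p_unc, size=L - n_at), D - 1
                )
            seg[:n_at] = covered_draw
            seg[n_at:] = uncovered_draw
            rng.shuffle(seg)
            depth[lo:hi] = seg
        profiles.append(DepthProfile(sample_id, footprint, depth))
        planted[sample_id] = tier_of
    return profiles, planted


def gen_variants(
    panel: GenePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    dropped_exon_ids: Sequence[str] = (),
) -> tuple[list[VariantRecord], CataloguePartition, int]:
    """Catalogue with planted class / position-multiplicity structure.

    Unique positions are sampled without replacement from exon bases; the
    multiallelic ones get a second record with a different alternate base.
    When `n_positions_in_noncaptured` is set, exactly that many unique
    positions are placed on bases belonging only to dropped exons (the
    rest avoid them), mimicking a variant catalogue that is sparse in the
    non-targeted exons.  Returns records, the planted partition and the
    planted count of positions in non-captured exons.
    """
    n_total = config.n_variants_total
    n_large = int(round(config.frac_large_indel * n_total))
    n_positional = n_total - n_large
    n_pos = int(round(n_positional / (1.0 + config.frac_multiallelic)))
    n_multi = n_positional - n_pos

    dropped = set(dropped_exon_ids)
    cap_bases: list[tuple[str, int, str]] = []  # (chrom, pos0, gene)
    nc_bases: list[tuple[str, int, str]] = []
    base_owner: dict[tuple[str, int], tuple[str, bool]] = {}
    for ex in panel.exons:
        is_dropped = ex.exon_id in dropped
        for p in range(ex.interval.start, ex.interval.end):
            key = (ex.interval.chrom, p)
            prev = base_owner.get(key)
            if prev is None or (not is_dropped and prev[1]):
                # a base shared with any non-dropped exon counts as captured
                base_owner[key] = (ex.gene, is_dropped)
    for (chrom, p), (gene, is_dropped) in base_owner.items():
        (nc_bases if is_dropped else cap_bases).append((chrom, p, gene))
    cap_bases.sort()
    nc_bases.sort()

    if config.n_positions_in_noncaptured is None:
        pool = cap_bases + nc_bases
        pool.sort()
        if n_pos > len(pool):
            raise ValueError("requested more unique positions than exon bases")
        chosen = [pool[i] for i in rng.choice(len(pool), n_pos, replace=False)]
    else:
        k_nc = config.n_positions_in_noncaptured
        if k_nc > len(nc_bases):
            raise ValueError(
                "requested more non-captured positions than non-captured bases"
            )
        if n_pos - k_nc > len(cap_bases):
            raise ValueError("requested more unique positions than exon bases")
        chosen = [nc_bases[i] for i in rng.choice(len(nc_bases), k_nc, replace=False)]
        chosen += [
            cap_bases[i] for i in rng.choice(len(cap_bases), n_pos - k_nc, replace=False)
        ]

    bases = "ACGT"
    patho = list(zip(("pathogenic", "likely_pathogenic", "VUS", "unknown"),
                     config.pathogenicity_mixture))
    labels, probs = zip(*patho)

    records: list[VariantRecord] = []
    vid = 0

    def _patho() -> str:
        return str(rng.choice(labels, p=probs))

    multi_idx = set(rng.choice(n_pos, n_multi, replace=False).tolist()) if n_multi else set()
    for i, (chrom, pos0, gene) in enumerate(chosen):
        pos1 = pos0 + 1
        ref = bases[int(rng.integers(4))]
        alts = [b for b in bases if b != ref]
        rng.shuffle(alts)
        n_alleles = 2 if i in multi_idx else 1
        for a in range(n_alleles):
            vid += 1
            records.append(
                VariantRecord(
                    variant_id=f"v{vid:06d}",
                    gene=gene,
                    variant_class=VariantClass.POSITIONAL,
                    chrom=chrom,
                    pos=pos1,
                    ref=ref,
                    alt=alts[a],
                    hgvs_c=f"c.{pos1}{ref}>{alts[a]}",
                    pathogenicity=_patho(),
                )
            )
    gene_list = sorted(panel.genes)
    for _ in range(n_large):
        vid += 1
        gene = gene_list[int(rng.integers(len(gene_list)))]
        a, b = sorted(rng.integers(1, 5000, size=2).tolist())
        records.append(
            VariantRecord(
                variant_id=f"v{vid:06d}",
                gene=gene,
                variant_class=VariantClass.LARGE_INDEL,
                hgvs_c=f"c.{a}_{b + 1}del",
                pathogenicity=_patho(),
            )
        )
    partition = CataloguePartition(
        n_total=n_total,
        n_large_indel=n_large,
        n_positional=n_positional,
        n_unique_positions=n_pos,
        n_multiallelic_positions=n_multi,
    )
    if config.n_positions_in_noncaptured is not None:
        k_nc_planted = config.n_positions_in_noncaptured
    else:
        nc_set = {(b[0], b[1]) for b in nc_bases}
        k_nc_planted = sum(1 for c in chosen if (c[0], c[1]) in nc_set)
    return records, partition, k_nc_planted


def gen_findings(
    panel: GenePanel, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[CaseFinding], list[CaseFinding], dict[str, str]]:
    """Findings for the two diagnostic cohorts with planted verdicts.

    The unknown-etiology cohort gets exactly the configured verdict counts
    (positive cases carry one pathogenic or likely-pathogenic finding and
    possibly VUS noise; uncertain cases only VUS; negative cases nothing);
    every known-etiology case carries one pathogenic finding.
    """
    genes = sorted(panel.genes)
    n_pos, n_unc, n_neg = config.planted_verdicts
    verdicts = ["positive"] * n_pos + ["uncertain"] * n_unc + ["negative"] * n_neg
    rng.shuffle(verdicts)
    unknown: list[CaseFinding] = []
    planted: dict[str, str] = {}
    fid = 0
    for i, verdict in enumerate(verdicts):
        sid = f"case{i + 1:02d}"
        planted[sid] = verdict
        if verdict == "positive":
            fid += 1
            label = "pathogenic" if rng.random() < 0.7 else "likely_pathogenic"
            unknown.append(
                CaseFinding(sid, f"f{fid:04d}", genes[int(rng.integers(len(genes)))],
                            label, "heterozygous")
            )
            if rng.random() < 0.5:  # incidental VUS must not change the verdict
                fid += 1
                unknown.append(
                    CaseFinding(sid, f"f{fid:04d}",
                                genes[int(rng.integers(len(genes)))], "VUS", "")
                )
        elif verdict == "uncertain":
            for _ in range(int(rng.integers(1, 3))):
                fid += 1
                unknown.append(
                    CaseFinding(sid, f"f{fid:04d}",
                                genes[int(rng.integers(len(genes)))], "VUS", "")
                )
        else:
            # enrolled but nothing reportable: empty variant_id marks the
            # case so the cohort file is self-contained
            unknown.append(CaseFinding(sid, "", "", "", ""))
    known: list[CaseFinding] = []
    for i in range(config.n_cases_known):
        sid = f"known{i + 1:02d}"
        planted[sid] = "positive"
        fid += 1
        known.append(
            CaseFinding(sid, f"f{fid:04d}", genes[int(rng.integers(len(genes)))],
                        "pathogenic", "heterozygous")
        )
    return unknown, known, planted


def simulate(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Run every generator under one seed; optionally write all files.

    Identical config + seed gives byte-identical output files.  Writes:
    panel.bed, design.bed, genes.txt, depth/<sample>.bed, manifest.tsv,
    variants.tsv, findings_unknown.tsv, findings_known.tsv,
    ground_truth.json, config.yaml.
    """
    r_panel, r_cap, r_depth, r_var, r_find = _rngs(config.seed, 5)
    panel = gen_panel(config, r_panel)
    design, dropped = gen_capture(panel, config, r_cap)
    profiles, planted_cats = gen_depth(panel, design, config, r_depth)
    variants, partition, k_nc = gen_variants(panel, config, r_var, dropped)
    unknown, known, planted_verdicts = gen_findings(panel, config, r_find)
    ds = SimulatedDataset(
        config=config,
        panel=panel,
        design=design,
        dropped_exon_ids=dropped,
        profiles=profiles,
        planted_categories=planted_cats,
        variants=variants,
        planted_partition=partition,
        planted_positions_in_noncaptured=k_nc,
        findings_unknown=unknown,
        findings_known=known,
        planted_verdicts=planted_verdicts,
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "depth").mkdir(parents=True, exist_ok=True)
        write_bed(
            (
                GenomicInterval(
                    ex.interval.chrom,
                    ex.interval.start,
                    ex.interval.end,
                    f"{ex.gene}|{ex.exon_id}",
                )
                for ex in panel.exons
            ),
            out / "panel.bed",
        )
        write_bed(design.targets, out / "design.bed")
        (out / "genes.txt").write_text("".join(g + "\n" for g in sorted(panel.genes)))
        with open(out / "manifest.tsv", "w") as fh:
            fh.write("sample_id\tdepth_path\tgroup\n")
            for p in profiles:
                write_depth_bed(p, out / "depth" / f"{p.sample_id}.bed")
                fh.write(f"{p.sample_id}\tdepth/{p.sample_id}.bed\tunknown_SCAD\n")
        write_variant_catalogue(variants, out / "variants.tsv")
        write_findings(unknown, out / "findings_unknown.tsv")
        write_findings(known, out / "findings_known.tsv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(ds.ground_truth(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        config.to_yaml(out / "config.yaml")
    return ds
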