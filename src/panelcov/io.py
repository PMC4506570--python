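"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain text:

* panel exons / capture targets — BED (3+ columns, 0-based half-open; for
  panel BEDs column 4 is ``GENE|EXON_ID``, or just the exon id);
* per-sample depth — either a 4-column per-base BED dialect
  (chrom, start, end, depth; run-length encoded) or a per-locus TSV with a
  1-based ``chrom:pos`` key and a depth column (the depth-of-coverage
  per-locus layout GATK emits);
* variant catalogue — 9-column TSV mirroring an HGMD-style export;
* sample manifest — TSV (sample_id, depth_path, optional group);
* reports — TSV plus a JSON superset.

Base-quality / mapping-quality read filtering is an upstream concern of
whatever produced the depth table; this module treats depths as final.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .intervals import (
    CaptureDesign,
    Exon,
    GenePanel,
    GenomicInterval,
    PanelFootprint,
)
from .variants import VariantClass, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DepthProfile",
    "SampleManifest",
    "read_bed_intervals",
    "read_panel_bed",
    "read_capture_bed",
    "read_gene_list",
    "load_sca_d_genes",
    "read_depth_table",
    "write_depth_bed",
    "read_variant_catalogue",
    "write_variant_catalogue",
    "read_manifest",
    "write_report",
    "write_bed",
]


class DepthProfile:
    """Per-base read depth for one sample over the panel exon footprint.

    Depth is stored as one dense ``int32`` vector indexed by the footprint;
    any base the source file did not mention has depth 0, and positions
    outside the footprint always read as 0.
    """

    def __init__(
        self,
        sample_id: str,
        footprint: PanelFootprint,
        depth: np.ndarray | None = None,
    ):
        self.sample_id = sample_id
        self.footprint = footprint
        if depth is None:
            depth = np.zeros(footprint.total_bases, dtype=np.int32)
        depth = np.asarray(depth, dtype=np.int32)
        if depth.shape != (footprint.total_bases,):
            raise ValueError(
                f"depth vector length {depth.shape} does not match the "
                f"footprint ({footprint.total_bases} bases)"
            )
        if depth.size and int(depth.min()) < 0:
            raise ValueError("read depths must be non-negative")
        self.depth = depth

    def get(self, chrom: str, pos0: int) -> int:
        """Depth at a 0-based position; 0 outside the footprint."""
        i = self.footprint.index(chrom, pos0)
        return int(self.depth[i]) if i >= 0 else 0

    @property
    def total_depth(self) -> int:
        return int(self.depth.sum())

    def items(self):
        """Iterate ((chrom, pos0), depth) over the footprint. For small data."""
        for chrom, start, end, off in self.footprint.blocks():
            for k in range(end - start):
                yield (chrom, start + k), int(self.depth[off + k])


@dataclass(frozen=True)
class SampleManifest:
    sample_id: str
    depth_path: Path
    group: str = ""


# ---------------------------------------------------------------------------
# BED / gene lists


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED file (columns chrom, start, end[, name])."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else ""
            try:
                out.append(GenomicInterval(fields[0], start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_panel_bed(path: str | Path, genes: Iterable[str] | None = None) -> GenePanel:
    """Build a :class:`GenePanel` from an exon BED.

    The name column encodes ``GENE|EXON_ID``; a bare name is used as both
    gene and exon id.  When `genes` is given it is the authoritative panel
    list (exons referencing other genes are rejected); otherwise the gene
    set is inferred from the exons.
    """
    exons: list[Exon] = []
    for iv in read_bed_intervals(path):
        if not iv.name:
            raise ValueError(f"{path}: exon BED rows need a name column")
        gene, _, exon_id = iv.name.partition("|")
        exon_id = exon_id or gene
        exons.append(Exon(GenomicInterval(iv.chrom, iv.start, iv.end), gene, exon_id))
    gene_set = list(genes) if genes is not None else sorted({e.gene for e in exons})
    return GenePanel(gene_set, exons)


def read_capture_bed(path: str | Path) -> CaptureDesign:
    return CaptureDesign(read_bed_intervals(path))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_sca_d_genes() -> list[str]:
    """The curated 103-gene sudden-cardiac-arrest/death panel shipped with
    the package."""
    text = resources.files("panelcov").joinpath("data/sca_d_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# depth tables


def read_depth_table(path: str | Path, panel: GenePanel) -> DepthProfile:
    """Read a per-sample depth table restricted to the panel footprint.

    Two layouts are auto-detected per file: per-base BED
    (chrom, start, end, depth — run-length rows expanded per base) and
    per-locus TSV (``chrom:pos<TAB>depth``, 1-based, header optional).
    Loci outside the footprint are ignored (their count is logged); a
    malformed row aborts with its line number.
    """
    footprint = panel.footprint
    depth = np.zeros(footprint.total_bases, dtype=np.int64)
    n_outside = 0
    sample_id = Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if lineno == 1 and not any(
                f.lstrip("-").isdigit() for f in fields[1:]
            ):
                continue  # header row such as "Locus<TAB>Total_Depth"
            if ":" in fields[0]:
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}: line {lineno}: per-locus rows need 2 columns"
                    )
                chrom, _, pos_s = fields[0].partition(":")
                try:
                    pos1 = int(pos_s)
                    d = int(fields[1])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed per-locus row"
                    ) from exc
                if d < 0:
                    raise ValueError(f"{path}: line {lineno}: negative depth")
                i = footprint.index(chrom, pos1 - 1)
                if i < 0:
                    n_outside += 1
                else:
                    depth[i] = d
            else:
                if lineno == 1 and len(fields) >= 4 and not fields[1].isdigit():
                    continue  # header row
                if len(fields) < 4:
                    raise ValueError(
                        f"{path}: line {lineno}: per-base BED rows need 4 columns"
                    )
                try:
                    start, end, d = int(fields[1]), int(fields[2]), int(fields[3])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: malformed per-base BED row"
                    ) from exc
                if start >= end:
                    raise ValueError(f"{path}: line {lineno}: empty interval")
                if d < 0:
                    raise ValueError(f"{path}: line {lineno}: negative depth")
                idx = footprint.index_array(fields[0], np.arange(start, end))
                inside = idx >= 0
                n_outside += int((~inside).sum())
                depth[idx[inside]] = d
    if n_outside:
        logger.info("%s: ignored %d loci outside the panel footprint", path, n_outside)
    return DepthProfile(sample_id, footprint, depth.astype(np.int32))


def write_depth_bed(profile: DepthProfile, path: str | Path) -> None:
    """Write non-zero depth as run-length encoded 4-column BED rows.

    Zero-depth bases are omitted: absent means depth 0 on re-read, so the
    round trip is exact.
    """
    with open(path, "w") as fh:
        for chrom, start, end, off in profile.footprint.blocks():
            seg = profile.depth[off : off + (end - start)]
            if not seg.size:
                continue
            # run boundaries where the depth value changes
            change = np.flatnonzero(np.diff(seg)) + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [seg.size]))
            for rs, re_ in zip(run_starts, run_ends):
                d = int(seg[rs])
                if d:
                    fh.write(f"{chrom}\t{start + rs}\t{start + re_}\t{d}\n")


# ---------------------------------------------------------------------------
# variant catalogue

CATALOGUE_COLUMNS = [
    "variant_id",
    "gene",
    "variant_class",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "pathogenicity",
]


def read_variant_catalogue(path: str | Path) -> list[VariantRecord]:
    """Read an HGMD-export-style 9-column variant TSV.

    Positional records must carry chrom+pos; coordinate-free large indels
    must not.  Records are returned in file order (stable).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing catalogue columns {missing}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cls = VariantClass(row.variant_class)
        except ValueError as exc:
            raise ValueError(
                f"{path}: line {i}: unknown variant_class {row.variant_class!r}"
            ) from exc
        chrom = row.chrom or None
        pos = int(row.pos) if row.pos else None
        try:
            records.append(
                VariantRecord(
                    variant_id=row.variant_id,
                    gene=row.gene,
                    variant_class=cls,
                    chrom=chrom,
                    pos=pos,
                    ref=row.ref,
                    alt=row.alt,
                    hgvs_c=row.hgvs_c,
                    pathogenicity=row.pathogenicity,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return records


def write_variant_catalogue(records: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOGUE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.gene,
                        r.variant_class.value,
                        r.chrom or "",
                        str(r.pos) if r.pos is not None else "",
                        r.ref,
                        r.alt,
                        r.hgvs_c,
                        r.pathogenicity,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> list[SampleManifest]:
    """TSV with header ``sample_id  depth_path  [group]``; relative depth
    paths are resolved against the manifest's directory."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "depth_path" not in df.columns:
        raise ValueError(f"{path}: manifest needs sample_id and depth_path columns")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"{path}: duplicate sample_id entries: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.depth_path)
        if not p.is_absolute():
            p = base / p
        out.append(
            SampleManifest(row.sample_id, p, getattr(row, "group", "") or "")
        )
    return out


# ---------------------------------------------------------------------------
# reports


def _normalize_report(table: pd.DataFrame) -> pd.DataFrame:
    """Round percentage columns (named ``*_pct`` / ``pct_*``) to 2 decimals."""
    table = table.copy()
    for col in table.columns:
        if col.endswith("_pct") or col.startswith("pct_"):
            table[col] = [round_half_up(float(v), 2) for v in table[col]]
    return table


def write_report(
    table: pd.DataFrame | Sequence[dict],
    path: str | Path,
    fmt: str = "tsv",
    meta: dict | None = None,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a tabular report deterministically.

    Rows are sorted by `sort_by` (default: every column, left to right),
    percentage columns are rounded half-up to 2 decimals, and the JSON
    rendering is a faithful superset of the TSV (same rows plus `meta`).
    Writing the same report twice yields byte-identical files.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    table = _normalize_report(table)
    if len(table):
        keys = list(sort_by) if sort_by else list(table.columns)
        table = table.sort_values(keys, kind="mergesort").reset_index(drop=True)
    if fmt == "tsv":
        cols = list(table.columns)
        is_pct = [c.endswith("_pct") or c.startswith("pct_") for c in cols]
        with open(path, "w") as fh:
            fh.write("\t".join(map(str, cols)) + "\n")
            for row in table.itertuples(index=False):
                fh.write(
                    "\t".join(
                        _cell(v, pct_col) for v, pct_col in zip(row, is_pct)
                    )
                    + "\n"
                )
    elif fmt == "json":
        payload = {
            "meta": meta or {},
            "rows": json.loads(table.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _cell(v, pct_col: bool = False) -> str:
    if pct_col:
        return f"{float(v):.2f}"
    if isinstance(v, float):
        return repr(v) if v != int(v) else str(int(v))
    return str(v)
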