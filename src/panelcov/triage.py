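"""Case-level diagnostic triage from pathogenicity-labelled panel findings.

A case is *positive* when any finding in a panel gene is pathogenic or
likely pathogenic, *uncertain* when its only findings are variants of
uncertain significance (VUS), and *negative* otherwise — including cases
with no findings at all.  Pathogenicity labels are inputs; nothing here
re-interprets variants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct

__all__ = [
    "Verdict",
    "CaseFinding",
    "TriageResult",
    "triage_case",
    "triage_cohort",
    "cohort_yield",
    "read_findings",
    "write_findings",
]

POSITIVE_LABELS = frozenset({"pathogenic", "likely_pathogenic"})


class Verdict(str, enum.Enum):
    POSITIVE = "positive"
    UNCERTAIN = "uncertain"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class CaseFinding:
    sample_id: str
    variant_id: str
    gene: str
    pathogenicity: str
    zygosity: str = ""


@dataclass(frozen=True)
class TriageResult:
    sample_id: str
    verdict: Verdict


def triage_case(
    sample_id: str,
    findings: Sequence[CaseFinding],
    panel_genes: Iterable[str] | None = None,
) -> TriageResult:
    """Apply the positive / uncertain / negative rule to one case.

    When `panel_genes` is given, a finding outside the panel is a contract
    violation and raises (triage is defined over panel genes only).
    """
    if panel_genes is not None:
        genes = set(panel_genes)
        for f in findings:
            if f.gene not in genes:
                raise ValueError(
                    f"finding {f.variant_id!r} in {f.gene!r} is outside the panel"
                )
    if any(f.pathogenicity in POSITIVE_LABELS for f in findings):
        verdict = Verdict.POSITIVE
    elif any(f.pathogenicity == "VUS" for f in findings):
        verdict = Verdict.UNCERTAIN
    else:
        verdict = Verdict.NEGATIVE
    return TriageResult(sample_id=sample_id, verdict=verdict)


def triage_cohort(
    findings: Iterable[CaseFinding],
    sample_ids: Iterable[str] | None = None,
    panel_genes: Iterable[str] | None = None,
) -> list[TriageResult]:
    """Triage every case; `sample_ids` names the full cohort so cases with
    no findings are still classified (negative)."""
    by_sample: dict[str, list[CaseFinding]] = {}
    for f in findings:
        by_sample.setdefault(f.sample_id, []).append(f)
    cohort = sorted(set(sample_ids)) if sample_ids is not None else sorted(by_sample)
    missing = set(by_sample) - set(cohort)
    if missing:
        raise ValueError(f"findings for samples outside the cohort: {sorted(missing)}")
    return [
        triage_case(sid, by_sample.get(sid, []), panel_genes) for sid in cohort
    ]


def cohort_yield(results: Sequence[TriageResult]) -> dict:
    """Verdict counts, exact fractions and display percentages for a cohort.

    Display percentages are rounded half-up to whole numbers (so they may
    sum to 100 +/- 1); the exact fractions are always carried alongside.
    """
    if not results:
        raise ValueError("cannot compute yield of an empty cohort")
    n = len(results)
    out: dict = {"n": n}
    for verdict in Verdict:
        count = sum(1 for r in results if r.verdict is verdict)
        out[verdict.value] = {
            "count": count,
            "fraction": count / n,
            "pct": pct(count, n, ndigits=0),
        }
    return out


FINDING_COLUMNS = ["sample_id", "variant_id", "gene", "pathogenicity", "zygosity"]


def read_findings(
    path: str | Path, with_cohort: bool = False
) -> list[CaseFinding] | tuple[list[CaseFinding], list[str]]:
    """Read a findings TSV.

    A row with an empty ``variant_id`` declares the case enrolled with no
    reportable findings (it will triage negative); such rows contribute to
    the cohort but not to the findings.  With ``with_cohort=True`` the
    full list of enrolled sample ids is returned alongside.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = [c for c in FINDING_COLUMNS if c != "zygosity"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing findings columns {missing}")
    findings = [
        CaseFinding(
            sample_id=row.sample_id,
            variant_id=row.variant_id,
            gene=row.gene,
            pathogenicity=row.pathogenicity,
            zygosity=getattr(row, "zygosity", "") or "",
        )
        for row in df.itertuples(index=False)
        if row.variant_id
    ]
    if not with_cohort:
        return findings
    return findings, sorted(set(df["sample_id"]))


def write_findings(findings: Sequence[CaseFinding], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FINDING_COLUMNS) + "\n")
        for f in findings:
            fh.write(
                "\t".join(
                    [f.sample_id, f.variant_id, f.gene, f.pathogenicity, f.zygosity]
                )
                + "\n"
            )
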