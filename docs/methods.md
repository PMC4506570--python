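# Methods

## Scope and model

`panelcov` treats a targeted-panel coverage audit as four deterministic
computations over three inputs: panel geometry (exon intervals tagged with
genes), a capture design (target intervals), and per-sample per-base read
depth over the panel footprint. Reads themselves are never seen: depth
tables are the contract, and whatever produced them (aligner, duplicate
marking, base/mapping-quality filters) is an upstream responsibility whose
settings the pipeline can record but does not apply. Variant pathogenicity
labels are likewise inputs, carried verbatim; the package performs no
variant interpretation.

### Coordinates

Intervals (exons, capture targets, depth BED rows) are 0-based half-open,
as in BED. Variant positions and per-locus depth keys are 1-based, as in
VCF/HGMD and depth-of-coverage per-locus output. Conversion happens in
exactly two places — exon membership lookup and depth lookup — so no other
code needs to know both conventions. Chromosome names are taken verbatim
from input files; no "chr"-prefix harmonization is attempted, because
silent renaming produces false zero-overlaps that are much harder to
diagnose than an obvious naming mismatch.

### Capture

A design is normalized on construction (per-chromosome sort, merge of
overlapping or bookended targets), so overlap queries are exact and the
union of targeted bases is represented once. An exon is **captured** iff
its total overlap with the union is at least `min_overlap` bases. The
default is 1: a non-captured exon is defined as one the kit did not target
at all, and any-overlap is the least-assuming operationalization; the
threshold is exposed because design-versus-exon edge effects are a real
ambiguity in published capture counts. Raising `min_overlap` can only
shrink the captured set (tested property).

A unique variant position lying in both a captured and a non-captured exon
(alternate transcripts) counts as captured: detectability is a property of
the base being targeted in at least one context. Positions in no panel
exon are reported separately and excluded from the captured/non-captured
split.

### Coverage tiers

For depth threshold D (default 20 reads, **inclusive** — "covered at 20x"
means depth ≥ 20), an exon's covered fraction is
f = |{bases with depth ≥ D}| / length. Tiers:

| tier   | condition        |
|--------|------------------|
| FULL   | f = 1.0 (exact)  |
| WELL   | 0.90 ≤ f < 1.0   |
| MOSTLY | 0.70 ≤ f < 0.90  |
| LIGHT  | 0.40 ≤ f < 0.70  |
| NONE   | f < 0.40         |

FULL is decided by the integer comparison `n_at == n_bases`, never by a
float threshold, so no exon can be promoted to FULL by rounding. The five
tiers partition [0, 1]; the boundaries are closed below and open above.

Per-sample tier proportions are computed over **captured exons only** by
default (configurable to all panel exons): the coverage question is posed
about exons the assay could in principle sequence, while non-captured
exons are already accounted for by the capture report. Proportions are
averaged unweighted across samples. Per-exon mean covered fraction across
samples requires every sample to report the exon, and a missing sample is
named rather than skipped.

The per-sample count of unique positions "stranded in no-coverage exons"
counts a position only when *every* containing classified exon is NONE in
that sample (best-tier rule, mirroring the captured-dominates rule).
Median over an even number of samples is the mean of the two central order
statistics.

### Detectability

Catalogue records split into positional records and coordinate-free large
indels. Large indels are structurally invisible to a per-base depth
argument and are surfaced in a dedicated "not assessable by this method"
section, never binned. Positional records collapse to unique
(chrom, pos) keys — a position sequenced at good depth is detectable
regardless of which base change is reported there — with per-record rows
still emitted. The per-position summary depth across samples is the
arithmetic mean rounded down (median available by config; the floor keeps
the binned quantity an integer read count). Bins: ≥ D adequate; 10–19x;
5–9x; < 5x. The two lower edges are fixed (they mirror the relaxed depth
cutoffs real calling pipelines use), so D must exceed 10 for the bins to
partition the non-negative integers.

### Triage

positive ⇔ any panel-gene finding labelled pathogenic or likely
pathogenic; else uncertain ⇔ any VUS; else negative (including cases with
no findings — the findings file marks enrolled-but-negative cases with an
empty variant id so a cohort file is self-contained). "Suspected
pathogenic" wordings in source material are mapped to likely_pathogenic.
Display percentages are rounded half-up to integers and may sum to
100 ± 1; exact fractions are always carried alongside. All report
percentages use half-up rounding (`decimal`), because banker's rounding
makes printed values depend on last-digit parity.

## Synthetic data generator

The generator emulates the observed structure of a 103-gene SCA/D exome
coverage study and is the package's test bed; its defaults are the study
conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_exons_total | 103 / 2,190 | panel scale |
| exon_length | 50–300 bp | typical coding-exon sizes |
| p_not_captured | 0.024 | Bernoulli capture dropout (≈ 52 of 2,190); an exact count can be planted instead |
| n_samples | 72 | coverage cohort size |
| depth_threshold | 20 | adequacy standard |
| category_mixture | .81 / .0504 / .0491 / .0339 / .0566 | planted tier mixture (FULL…NONE) |
| covered_depth_mean | 100 | sequencing averaged ~100x |
| n_variants_total / frac_large_indel | 11,452 / 1896⁄11452 | catalogue scale and class mix |
| frac_multiallelic | 978⁄8578 | share of positions with ≥ 2 records |
| planted_verdicts | 5 / 16 / 9 of 30 | diagnostic cohort composition |

Each gene sits on its own synthetic chromosome (`chrS1`, …) with
non-overlapping exons; no real-genome coordinates are imitated, which
prevents accidental conflation with real annotation.

Depth planting has two modes. In **exact** mode every sample assigns tiers
to captured exons by largest-remainder quota over the mixture (shuffled
per sample), and each exon gets exactly a tier-consistent number of bases
at/above threshold — so classifier recovery is an identity check and
per-sample tier proportions equal the quota exactly. In **stochastic**
mode tiers are drawn i.i.d. from the mixture and per-base depths are drawn
from negative-binomial-shaped noise truncated to the planted tier's
fraction band: per-exon recovery is still exact (the band is respected by
construction), while per-sample proportions fluctuate multinomially, so
cross-sample means are checked against the mixture within three
Monte-Carlo standard errors estimated from the run itself. This separates
logic verification (exact mode) from distributional realism (stochastic
mode).

Catalogue generation places unique positions uniformly over exon bases
(optionally planting an exact count of positions restricted to
non-captured exons, for studies whose catalogues are sparse there);
multiallelic positions receive a second record with a different alternate
base. Non-captured exons get depth 0 everywhere. Everything is driven by
one `numpy` SeedSequence: identical config + seed gives byte-identical
output files.

### What the generator does *not* emulate

Real capture data has GC- and mappability-driven coverage structure that
is correlated along the genome and *between* samples (the same hard exons
fail everywhere), and real variant catalogues concentrate variants in
well-studied, generally well-covered exons. The generator's dropout, tier
assignment and variant placement are independent draws. Consequently,
passing tests demonstrate that the *computations* are correct on data of
realistic scale and composition — they do not demonstrate that any
particular assay reaches the planted rates, and cross-sample statistics
that depend on between-sample correlation (e.g. the spread of per-sample
no-coverage position counts) will be narrower in synthetic data than in
real cohorts.

## Numerical choices

* Percentages: half-up rounding; 1 decimal in capture/catalogue reports,
  2 decimals in tabular report files, integers for cohort yields; raw
  counts and exact fractions are always emitted next to any rounded value.
* Depth storage: one dense `int32` vector per sample over the merged panel
  footprint (a few hundred kB at study scale), with absent = 0; per-exon
  counting is a cumulative-sum slice, so classifying 2,190 exons × 72
  samples takes about a second.
* Interval merge treats bookended intervals (end = next start) as one run
  of bases; merge is idempotent and base-count preserving (tested against
  a per-base union oracle).
* Degenerate inputs: empty depth file = all-zero profile (valid); empty
  capture design = nothing captured (valid); empty panel, empty stat
  lists, and empty cohorts are errors, because their downstream ratios are
  undefined.

## Problem sizes used in the checks

Randomized oracle comparisons run on fixtures up to ~10⁴ bases and ~10³
catalogue records against exhaustive per-base / per-record loops.
Planted-recovery checks run at full study scale (103 genes, 2,190 exons,
72 samples, 11,452 catalogue records) in both depth modes; the whole
suite, including those, completes in well under a minute on one CPU.

## Known limitations

* Capture is binary at the exon level; probe-level efficiency and
  continuous enrichment models are out of scope.
* Detectability is a depth argument only: no genotype quality, allele
  balance, or indel-realignment modelling, and CNVs/large indels are
  reported as not assessable rather than solved.
* The per-variant summary statistic across samples (mean, floored) is a
  reporting choice; published per-variant depths rarely state theirs, so
  the statistic is configurable and recorded in the report.
* Whether published tier proportions used all panel exons or captured
  exons as denominator is often ambiguous; both modes are supported
  (`captured-only` is the default) and the choice is recorded in the
  report provenance.
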