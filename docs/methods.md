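# Methods

## The purity mixture model

A tumor sample contains malignant cells at fraction `p` (purity, supplied a
priori by the analyst) and normal cells at `1 − p`. All somatic signals the
package calls are convex combinations of the two compartments:

- **Coverage.** A region with true tumor copy number `CN_t` over diploid
  normal has expected observed copy number
  `CN_obs = p·CN_t + (1 − p)·ploidy`. The inverse,
  `CN_t = round((CN_obs − (1 − p)·ploidy) / p)`, is the calibration applied
  to every reported CNV. Rounding ties (residual exactly 0.5) round *away*
  from the normal ploidy, preferring to report an event over silence; the
  tie-break is pinned by a test. Calibration is undefined at `p = 0` and
  raises.
- **Allele fractions.** A site with `a_t` of `c_t` alternate copies in tumor
  and `a_n` of `c_n` in normal has expected VAF
  `(p·a_t + (1 − p)·a_n)/(p·c_t + (1 − p)·c_n)`. For a germline het inside
  copy-neutral LoH this gives `(1 + p)/2` (alt retained) or `(1 − p)/2`
  (alt lost); the het band stays at `1/2`. Deletion-LoH expectations (one
  retained copy) are available behind a flag; copy-neutral is the default
  because it is the conservative assumption when coverage is uninformative.
- **Methylation.** A window with normal methylated fraction `m` and tumor
  shift `Δ` is observed at `m + p·Δ`; tumor content attenuates differential
  signal linearly.

**Site classification.** A tumor site at a germline-het position is compared
to the three bands {ref-lost, het, alt-retained} at a tolerance of 0.10 in
VAF space. The het band takes precedence: any fraction within tolerance of
0.5 is called het even if a hom band is numerically nearer, because once the
band separation `p/2` falls below the tolerance the classes are genuinely
indistinguishable and het is the conservative call. This choice makes the
sensitivity collapse below ~50% purity explicit rather than letting noise
masquerade as LoH support. An optional depth-aware tolerance
(`2·sqrt(f(1 − f)/depth)`) is provided for high-depth data. Zero-depth sites
are uninformative (ambiguous), not errors.

## CNV calling

Coverage arrives as mean depth over fixed 1 kb windows (the format produced
by standard depth summarizers). The tumor/normal ratio per bin is
`(d_t/median_t)/(d_n/median_n)` with genome-wide medians, so a flat diploid
genome sits at ratio 1 regardless of sequencing yield; the median is robust
while aneuploid events cover under half the genome. Blacklisted bins and
bins with zero normal depth are dropped (a warning fires when more than half
the bins are removed). Tumor-only mode normalizes by the tumor's own median.

Segmentation is recursive binary splitting on log2(ratio): the best split of
a segment is the one maximizing the reduction in within-segment sum of
squared deviations (computed in O(n) via prefix sums), accepted while the
reduction exceeds a penalty. The default penalty is `10·σ̂²`, with `σ̂`
estimated from the scaled median absolute deviation of bin-to-bin log2
differences divided by √2 (differencing removes copy-number structure; a
difference of independent bins doubles the variance). Segments shorter than
the minimum size are merged into the neighbor with the nearest mean until
none remain. Chromosomes are processed independently in order of first
appearance; no segment or call ever crosses a chromosome boundary. On tracks
with well-separated steps the greedy splitter provably coincides with the
exhaustive SSE optimum, which the test suite checks directly against an
enumeration oracle.

Segments become calls via `CN_obs = ratio × ploidy` and the inverse
calibration. Suppressed: segments whose calibrated CN equals the normal
ploidy, whose |log2 ratio| is inside a neutral band (default 0.1), or whose
span is under the size floor — 100 kb in paired mode, 1 Mb in tumor-only
mode, where the lack of a matched normal demands prioritizing large events.

## LoH detection

Seeds are sites heterozygous in the normal: genotype het *and* allele
fraction in [0.30, 0.70] (the input SNV filter keeps only PASS biallelic
SNVs with AF > 0.10, which alone does not guarantee a balanced het). Each
seed is classified in the tumor; maximal runs of adjusted-homozygous sites
become regions, spanning first to last supporting site, subject to:

- at least `min_sites` = 25 supporting sites (at ~1 het/kb this is ≥ ~25 kb
  of evidence),
- persistent-het fraction ≤ `max_het_frac` = 0.15 of classified sites,
- ambiguous sites tolerated up to half the run — a stretch dominated by
  unclassifiable fractions (e.g. allelic imbalance inside an unrelated CNV)
  is not LoH evidence,
- at most 10 consecutive non-supporting sites, so a long run cannot drift
  past its true boundary on trailing noise.

Sex chromosomes are excluded by default (ploidy ambiguity). Tumor-only mode
scans the tumor's own sites for runs in the adjusted-hom bands and raises
the size floor to 1 Mb. Regions overlapping a CNV call get their
`concurrent_cn` annotated, so copy-neutral and deletion-LoH are
distinguishable downstream; no merging of CNV and LoH events is attempted.

Benchmark matching (`match_calls`) follows interval-intersection practice:
a truth interval is recovered when one call covers ≥ 70% of *its* length,
boundary inclusive.

## Differential methylation

Per-CpG modified/valid counts are pooled over non-overlapping 10 kb windows
anchored at coordinate 0 per chromosome; a window's fraction is pooled
modified over pooled valid calls — pooling (rather than averaging per-site
fractions) weights sites by evidence and is robust to uneven depth. Windows
with fewer than 5 valid calls are unassessed. A window is a cDMR when both
fractions are defined and they differ by ≥ 33 percentage points (inclusive);
the sign gives the direction. Self-comparison is empty and swapping samples
flips every call, both pinned by tests.

The 33-pp operating point is reproducible from a cohort of normals:
over all unordered sample pairs, count windows exceeding each integer
threshold t ∈ 0..100 and return the smallest t whose mean per-pair count
falls to a target (~50) — the difference level at which same-tissue,
different-individual comparisons stop producing candidates. The calibration
is monotone in the target by construction.

Tumor-only support: per-window extreme classification (≥ 90% methylated =
high, ≤ 10% = low, both inclusive) and a panel-of-normals reference taking
the per-window median fraction (even counts: mean of the central pair)
across panel samples, requiring 3 defined samples per window (or the whole
panel when smaller). Cohort intersection (`constitutive_regions`) returns
windows called in a fixed direction in *every* sample.

## Allele-specific methylation

Genes from a configured panel are padded by 2 kb on both sides (promoters),
clamped at the chromosome start. Haplotagged CpG records build one windowed
series per (sample, haplotype, gene) at 1 kb resolution — genes are short,
so the genome-wide 10 kb grid would be too coarse. Unphased records are
excluded. The four series are compared in all six unordered pairs; a pair's
statistic is the largest absolute window difference, and the ASM flag is
raised only for within-sample pairs (tumor H1 vs H2, normal H1 vs H2) at the
same 33-pp threshold; no separate ASM threshold is introduced. Cross-sample
pairs report haplotype-resolved tumor-normal change without the flag. A
series with median per-CpG coverage below 5 is not assessable — deliberately
so, since an allele lost to LoH manifests exactly as a tumor series with few
haplotagged reads, and reporting a methylation difference there would
confuse loss with demethylation.

## HLA-LoH

Inputs are read counts per typed allele (two-field resolution; names are
truncated on input) in tumor and normal. The score is the allele-1 read
fraction difference `Δr = r_tumor − r_normal`. Under copy-neutral loss at
purity `p` the lost allele's fraction moves from 1/2 to `(1 − p)/2`, a full
shift of `p/2`; the default decision threshold is half that, `p/4`, the
midpoint between no-LoH and full LoH, so sensitivity scales with stated
purity rather than using one fixed cut. Germline-homozygous genes
short-circuit (no ratio is meaningful); genes with under 10 reads in either
sample are no-calls. A two-sided Fisher exact p-value on the 2×2 count table
is emitted as an auxiliary column but never drives classification. In
tumor-only mode, homozygous two-field typing is flagged as a *hint* of
somatic loss — it cannot be distinguished from germline homozygosity without
a normal.

## Somatic SVs

Two SV records match when they share chromosome and type, their breakpoints
are within 1000 bp (inclusive), and their sizes agree within a 0.7
min/max ratio (skipped for breakends). Events whose spans exceed 10× the
breakpoint-distance cap may instead match by ≥ 0.7 reciprocal interval
overlap — large events jitter at the breakpoint more than they move as
intervals. Insertions are judged by position and length only. Tumor-normal
subtraction greedily pairs nearest breakpoints first, each normal record
consumable once; unmatched tumor records are somatic, and
|somatic| + |shared| = |tumor| always. On small instances the greedy
matching is verified against a brute-force maximum-matching oracle.
Tumor-only prioritization keeps records with zero population-index hits
("pseudo-somatic"); records the index cannot resolve are labeled unknown and
conservatively excluded.

## Synthetic data

The simulator produces the summary tracks the callers consume, never reads:

- coverage bins ~ Poisson(30 × expected CN / ploidy) at 1 kb,
- germline-het SNVs at 1 site/kb with Binomial(depth, expected VAF) alt
  counts per compartment state,
- methylation windows with Binomial(n_valid, fraction) modified counts at
  ~2700 valid calls per 10 kb window (≈ 9 CpGs/kb at 30× — human-realistic
  CpG density; at this mass the binomial noise on a window fraction is
  ~1 pp, so a 40-pp planted effect is cleanly separable from the 33-pp
  threshold),
- SVs as jittered call records (germline in both samples, somatic in tumor
  only; jitter ≤ 500 bp),
- HLA counts ~ Binomial from copy proportions (retained `1 + p`, lost
  `1 − p`).

Default genome: 10 chromosomes × 10 Mb — room for ≥ 1 Mb events on the 1 kb
grid while keeping full-ladder recovery tests to seconds per seed. The
titration operator mixes a *pure* tumor with its normal at fraction α by
binomially thinning each compartment's read counts (keep α and 1 − α), so
VAFs and methylated fractions mix as real sequencing mixtures do rather
than by averaging fractions; expected coverage mixes exactly linearly. All
randomness flows from one seed; identical seeds give bit-identical exports
(gzip mtime pinned).

What the simulator does **not** emulate: GC and mappability bias, replication
timing waves, subclonal heterogeneity (every somatic event is clonal),
segmental duplications and mapping artifacts, CpG-density variation and
hemimethylation, overdispersed (non-Poisson) depth, and SV callers' breakend
ambiguity. Passing recovery tests therefore demonstrates correctness of the
calibration and calling logic under the stated noise model, not robustness
to real-genome artifacts — the blacklist input and the configurable
thresholds are the hooks for the latter.

## Numerical and degenerate-input choices

- In-memory coordinates are 0-based half-open everywhere; conversion happens
  only at the VCF boundary (POS = start + 1). Property tests round-trip both
  representations.
- Multi-allelic SNV records are rejected, not decomposed.
- Allele fraction comes from the caller's AF/VAF annotation when present,
  else alt/total from AD; a VCF with neither raises with an instruction.
- Output files sort records by (chromosome, start) and fix float formats, so
  identical inputs give identical bytes.
- Empty inputs produce empty outputs (or header-only files), not errors;
  zero shared het sites in LoH detection warns and returns empty.
- Contigs are processed in coverage-track order; no karyotype sort imposed.

## Test problem sizes

Unit and property tests run on kb–Mb toy tracks. The acceptance-level suite
uses a 100 Mb genome (10 × 10 Mb) with 10 planted CNV/LoH events ≥ 1 Mb over
5 seeds and the full 90→10% titration ladder, 10 Mb cDMR cohorts over 5
seeds, 100 HLA replicates per purity, and 50-record SV instances — sizes
chosen so the whole suite completes in a few minutes on one CPU while the
law-of-large-numbers margins stay comfortable.
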