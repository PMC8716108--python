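# Methods

## The measurement model

Term-seq counts exposed RNA 3′ ends per nucleotide and strand. At an
efficient terminator these counts drop abruptly across the four nucleotides
flanking the termination site — the TTS quadruplet −2, −1, +1, +2, with the
TTS at −1 and no position 0. All statistics in this package are functions of
quadruplet counts:

* termination efficacy `TTE = 1 − reads[+2]/reads[−2]`. TTE is
  scale-invariant in sequencing depth, bounded above by 1, and deliberately
  *not* clamped below 0: negative values (readthrough exceeding the
  upstream signal) are retained so that group medians see them.
* factor dependency `TQRR = (WT[+2]/WT[−2]) / (dep[+2]/dep[−2])`, the
  wild-type readthrough ratio over the depletion strain's. TQRR < 1 ⟺
  TTE_WT > TTE_dep (an algebraic identity our property tests assert), so
  TQRR < 1 marks termination that depends on the depleted factor.

TUs with a zero denominator in either statistic are recorded as
unevaluable, counted in the run summary, and excluded from group
statistics.

## TTS calling

Search is confined to the 200 nt immediately 3′ of each coding gene's stop
codon, which suppresses 3′ ends from RNA processing and decay elsewhere in
the transcript. A position is a candidate when, in a single replicate of
the reference condition, the −1/+1 count ratio exceeds 1.1 **and** the
count difference exceeds 5; a nonzero −1 count over a zero +1 count passes
the ratio test, since the inequality means "−1 exceeds +1 by more than
10 %". Sites must pass in **both** replicates. Because "high coverage" is
not quantified in the source analysis, we add a configurable minimum −1
count per replicate (default 10), applied after the two printed filters and
reported in the run summary. Candidate detection uses only the reference
(wild-type) tracks; the depletion condition enters solely through TQRR.

Per TU, the consensus site with the highest replicate-mean −1 count is the
primary TTS (ties break toward the site closest to the stop codon — the
upstream-most, most conservative choice); all others are secondary.
Quadruplet counts are replicate means by default (`pooled` sums are a
config option); the mean keeps TTE on the per-replicate scale and the two
choices give identical TTE when replicates have equal depth. 3′UTR length
is the distance from the first nucleotide after the stop codon through the
TTS inclusive (adjacent TTS → 1). Sites inside a neighboring annotated CDS
are retained but flagged, since 200-nt windows can overlap neighbors in
compact genomes. ncRNA mode applies identical filters inside user-supplied
windows.

## Terminator U4-tracts and motif matrices

A U4-tract is a **maximal** run of ≥ 4 consecutive uridines in the
RNA-sense window −31..−1 (31 nt, TTS included): a U5 or U7 run is one
tract, two runs separated by a non-U are two. This maximal-run convention
matches how single U5/U4 runs are treated as single tracts in reporter
terminators, and is verified against an independent run-scan oracle on
random sequences. N breaks a run and contributes to no base column. TUs are
grouped by tract count 0/1/2/>2; where a "≥ 2" or "≥ 1" union is needed it
is derived on demand rather than changing the four-way partition.

Motif matrices cover −30..+5 (35 nt): per-position base counts and
information content `2 − H` bits, H the Shannon entropy of the position's
base frequencies, with no small-sample correction. Clipped windows (TTS too
close to a genome end) are flagged and excluded. A log-odds PWM match score
against the primary-TTS matrix is provided as a clearly optional extra; it
is not part of the core statistics.

## Group statistics

Spearman correlation (average ranks for ties; large-sample p) relates
U4-tract counts to TTE. Between-group comparisons use the two-sided
Wilcoxon rank-sum test: exhaustive enumeration of all C(n+m, n) assignments
when n+m ≤ 12 (midranks handle ties; two-sided p is the permutation mass at
least as far from nm/2 as observed), otherwise the normal approximation
with tie and continuity correction; the two routes agree within 0.02 at the
crossover sizes. Quartiles use linear interpolation between order
statistics (type 7), recorded in output metadata because the convention
affects small groups. Text output floors p-values at 2.2e−16 while the raw
float is kept. Pairwise p-values are reported raw by default; Holm
correction is a flag.

Boundary policy: the strict inequalities of the published group definitions
leave 0.3/0.6 (TTE) and nothing for TQRR = 1 ambiguous at the edges; a
boundary value joins the higher class (TTE 0.6 → high, 0.3 → medium;
TQRR 0.6 → highly, 1.0 → non). This makes both classifications total
partitions of the line, which the tests assert.

## The synthetic-data generator

The generator encodes the study conditions the analysis assumes, so
pipeline behaviour can be measured against planted truth.

* **Genome/annotation.** TUs alternate strands along a random background
  (GC 0.33, AT-rich like the methanogen genome this models). Each TU's
  terminator window −31..−1 is written with exactly the drawn number of
  maximal T-runs (RNA U-runs) of length 4–7; filler positions come from
  {A, C, G} so no accidental run can form or merge planted runs. The planted
  TTS sits 20–150 nt after the stop codon, inside the 200-nt search window.
* **Coverage.** In transcription direction the 3′-end mean is a plateau λ
  from −60 to −2, a peak λ(1+c·e) at −1 (c = 3 by default, making the drop
  filters fire at realistic depths), and a readthrough tail λ(1−e) over
  +1..+30, plus a uniform background ε = 1 everywhere; counts are Poisson
  (negative-binomial optional for overdispersion robustness; a noise-off
  debug mode emits the rounded means). λ per TU is uniform in λ₀·[0.5, 1.5].
  This plateau/peak/tail shape is the minimal generative model under which
  the TTE statistic is identifiable and the calling filters meaningful.
* **Planted parameters.** Mean efficacy per U4 group is 0.300, 0.433,
  0.521, 0.555 for 0/1/2/≥3 tracts (the observed per-group medians in the
  archaeal Term-seq study this package is built around), with Gaussian
  jitter (sd 0.05). Depletion multiplies efficacy by (1−δ) with δ = 0.20,
  0.35, 0.50, 0.55 increasing over U4 groups, so dependency is higher where
  tracts are more numerous. U4 counts are drawn with weights
  0.19/0.40/0.26/0.15 over 0/1/2/3, matching the observed ~19 % zero-tract
  fraction with the remainder spread plausibly (the source does not print
  the full split).
* **Determinism.** All randomness derives from `SeedSequence([seed, …])`
  keyed by stage, condition, replicate and strand; identical configs give
  byte-identical FASTA/GFF3/bedGraph/TSV outputs.

What the simulator does **not** emulate: RNA processing and degradation 3′
ends beyond the uniform background, operon structure and overlapping TUs,
depth differences between replicates, positional sequencing biases, and
secondary-structure effects. Passing recovery tests therefore demonstrate
the estimators and filters are correct under the assumed signal model, not
that the model captures every feature of real Term-seq libraries.

## Problem sizes and numerical choices

Recovery and correlation tests run the full pipeline on 200 TUs at plateau
depth 500 with two replicates — enough for per-group bias estimates with
standard error well below the 0.02 bias bound while keeping the default
test suite in seconds. Calibration checks use depths 50–2000 to show the
ratio-estimator bias shrinking with depth (at ε = 1 the leading TTE bias is
≈ −e·ε/λ). The acceptance script uses the same 200-TU/depth-500
configuration seeded from its `--seed`.

Degenerate inputs are defined, not silent: zero-length ncRNA windows yield
no calls, empty TTS tables round-trip as header-only TSVs, all-clipped
motif input raises, constant samples make Spearman an error, and
bedGraph overlaps, negative counts and out-of-genome coordinates are
format errors naming the offending line.

## Known limitations

* The primary/secondary distinction rests purely on the −1 read maximum;
  external criteria used in earlier TTS catalogs are not reproduced.
* Raw counts are used throughout; replicate depth normalization is not
  applied (TTE and TQRR are per-TU ratios and scale-invariant, but the
  replicate-mean quadruplet combination weights deeper replicates more).
* The readthrough tail end of a simulated TU also satisfies the drop
  filters and is called as a secondary site — a faithful consequence of the
  filter definition, which is why recovery is scored on primary sites.
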