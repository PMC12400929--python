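# Methods

This note documents the models and procedures implemented in `halovar`,
the defaults they run with, the numerical conventions that make results
reproducible, and what the synthetic benchmark does and does not show.

## Sequence identity conventions

All coordinates are 0-based half-open; SAM positions are converted at
the parsing boundary. Alignment identity is always computed over
alignment columns with indel columns counted as differences
(`identity = 100·(columns − NM)/columns`), the convention of mapper NM
tags. A 150 bp read therefore passes the 99.3% genomovar filter with at
most one mismatch (99.33%) and fails with two (98.67%).

## Fragment ANI and ANIr

`fragment_ani` cuts the query genome into non-overlapping 1000 bp
windows and aligns each end-free (edlib, infix mode) to its best
location in the subject. Fragments pass with ≥70% identity over ≥70%
aligned span; the directional ANI is the mean identity of passing
fragments and the reported ANI is the mean of the two directional means,
which bounds the asymmetry of the statistic (observed < 0.1 points on
random pairs). If no fragment passes in either direction the result is
flagged undefined (NaN) rather than 0 — unrelated sequences have no ANI.
Alignment is banded in two stages (band 6% of the fragment first, then
the full band implied by the identity floor) purely for speed; results
are identical.

`anir` takes each read's best alignment on one reference, keeps those
inside an identity window (default [95, 100], the species-level mapping
filter), and returns their mean identity. On genomes without indels,
fragment ANI agrees with global Hamming identity to ±0.05 points
(property-tested), and ANIr of a 50:50 two-genomovar mixture equals the
closed-form mixture mean.

## Competitive recruitment and TAD80

Reads are mapped against all genomovar representatives, filtered by
identity, and assigned winner-take-all: highest identity, then longest
alignment. Residual ties across references are real and frequent at
genomovar distances — at 99.0% inter-ANI a 150 bp read has
0.99¹⁵⁰ ≈ 22% probability of falling in a locally identical window.
`competitive_assign` supports two tie policies:

* `random` (uniform, seeded) — unbiased per read, but it provably
  flattens abundance *shares*: ties move mass from abundant to rare
  references (an expected +70% relative error on a 0.1-weight member of
  a 3-genomovar panel).
* `drop` (default on the abundance path) — ambiguous reads are credited
  to no reference. Retention is symmetric across references, so shares
  stay proportional to the truth; the positions that lose coverage are
  the locally conserved ones, and the TAD lower-tail trim absorbs them.

With `drop`, a 0.6/0.3/0.1 mixture at 99.0% inter-ANI and ~50×
panel coverage is recovered within a few percent relative, and
cross-genomovar assignment stays far below 5%.

TAD80 sorts the per-position depth vector, removes `floor(0.10·L)`
positions from each tail and averages the rest (`floor` stated so the
statistic is exact on small L). Effort normalization is
`TAD80 / total_reads × 10⁸`; raw TAD80 below 10× flags the entry out of
downstream statistics. Gene copy number is gene TAD80 over whole-species
TAD80 in the same sample.

A built-in exact-k-mer-seeded, ungapped mapper handles the
substitution-only synthetic reads so no external aligner is needed in
tests; SAM from a production mapper is the real input path (NM or MD
required; unmapped skipped; secondary alignments kept and flagged).

## Genomovar delineation

MAGs pass a quality gate (completeness ≥50%, contamination <10%;
quality score = completeness − 5×contamination selects representatives).
Genomes are clustered by average linkage on distance 100 − ANI with the
tree cut strictly below 0.5, so members sit above 99.5% ANI while
between-cluster ANI ≤99.5 separates. Clusters are labelled by
descending size with lexicographic tie-breaks, making the partition
invariant to input order. Shared-gene fraction between genomes uses the
*smaller* gene set as denominator, so MAG incompleteness does not
deflate it; it is reported, not used as a clustering criterion.

## Pangenome

Orthology groups are built CD-HIT style: genes sorted longest-first,
each joining the best-matching existing representative at ≥90% identity
over ≥70% of the shorter sequence (best-cluster assignment), else
founding a group. Occurrence classes follow p = n/N with the
genome-specific class (n = 1) taking precedence; N = 1 degenerates to
core. Openness is the log–log least-squares slope γ of the
permutation-median rarefaction curve (20 permutations by default, seeded);
identical gene sets give γ = 0, fully disjoint sets γ = 1.

## vOTU dereplication

Contigs ≥5000 bp are dereplicated greedily longest-first: a contig joins
the first cluster whose representative it matches at ≥95% identity over
≥85% of the shorter sequence ("shorter" read as the shorter of the pair,
which at clustering time is the incoming contig). The founding, longest
contig represents the vOTU. Lytic/temperate labels and host predictions
are treated as external annotations, not computed here.

## Local similarity analysis

Series are rank-transformed to normal scores at quantiles
(rank − 0.5)/n (average ranks on ties; interior gaps of ≤2 missing
points linearly interpolated, longer gaps disqualify the series;
constant series are rejected). The LS score is the classic dynamic
program over aligned index pairs within a delay bound D: positive and
negative partial sums of score products, reset at zero, maxima tracked;
the score is the larger maximum divided by n, signed. Ties break toward
the smallest |delay|, then the smaller delay, then the earliest window.
D defaults to 3 samples (±6 weeks at the two-week cadence).

Significance: the permutation p-value is
(1 + #{|LS<sub>perm</sub>| ≥ |LS<sub>obs</sub>|})/(1 + n_perm). The
default theoretical p-value rests on the observation that √n·|LS| is
asymptotically the **range** of a standard Brownian motion on [0, 1]
(the maximal positive partial sum is the walk's largest drawup, the
negative one its largest drawdown, and their maximum is the range), with
Feller's alternating series for the range CDF. Two finite-sample
corrections are applied, both calibrated once against the exact
permutation null and then frozen: the statistic is inflated by
(1 + 1.13/√n) (discrete walks undershoot continuous barriers), and the
delay search multiplies the tail through an exponent (1 + 0.1·D) on the
CDF — the 2D+1 shifted diagonals are almost fully dependent under
permutation, so the naive independent-diagonal exponent overstates the
tail several-fold. On the n ∈ {30, 50} grid the formula tracks
10⁴-permutation p-values within ~25% for p ∈ [10⁻³, 0.5], and
permutation p-values are uniform under the null (KS-tested).

Benjamini–Hochberg runs over the full pair set; an edge is significant
only as the conjunction |LS| ≥ 0.6 ∧ P ≤ 0.05 ∧ Q ≤ 0.01.

## Viral cohorts

Significant edges form a weighted graph (weight |LS|, sign kept as an
attribute since MCL needs non-negative weights); host genomovar series
are included as nodes so cohort–host linkage emerges from the clustering
itself. MCL uses expansion 2, inflation 2.0, self-loops, pruning 1e-5,
and a fixed node order with lexicographic attractor tie-breaks, making
the partition deterministic; non-convergence raises. A cluster with one
host is that genomovar's cohort; several hosts are resolved by the
highest mean |LS| to the cluster's vOTUs; host-free clusters stay
unassigned. Cohort abundance is the per-sample sum of member vOTUs.

## The synthetic generator

**Genomes.** An ancestor of whole 1 kb gene blocks diverges along a star
tree whose per-genomovar branch lengths are the closed-form least-squares
fit to the target ANI matrix; matrices that are not star-additive within
0.15 ANI points are rejected with the offending triple named. Strain
branches (half the within-genomovar divergence, default 0.3% → within-ANI
≈99.7%) are carved out of the genomovar branches so realized
between-genomovar identity still meets the targets; the default target
matrix is the reported inter-genomovar mean ANI of the four Hqrw
genomovars, which is star-additive to ≈0.08 points. Gene content hits a
scalar shared-fraction target (default 85%) exactly through one core set
plus disjoint genomovar-specific sets; per-pair target matrices are not
supported. Substitution-only divergence suffices because every statistic
downstream (ANI, shared-gene fraction, recruitment identity) is
insensitive to synteny.

**Reads.** Uniform starts, substitution-only errors at a flat rate,
sampled proportional to weight × genome length, with a truth table of
source and planted error count. No paired-end inserts, no quality-score
realism.

**Ecology.** Daily Euler updates (Δt = 1 d over 813 d) of a forced
Lotka–Volterra system: hosts grow logistically with a shared carrying
capacity (K = 70) under a growth rate shaped by two environmental axes —
a sawtooth salinity (instant dilution to the regime floor, 13% or 20%
salts, every 200 d; linear evaporation back to 36%) and a seasonal
temperature cycle (22 ± 8 °C, period 365 d) — minus predation by their
cohort (infection a = 0.002, burst 10, decay 0.4 d⁻¹, small immigration
0.05 units/d to avoid absorbing extinctions). Each of the four hosts
occupies a distinct salinity × temperature niche; the two-axis design is
what makes four cohorts separable at the default delay window, because a
±6-week delay search erases phase separation within a single 200-day
salinity cycle. Initial host abundances are the study's day-0 genomovar
percentages. Member vOTU series are fixed Dirichlet proportions of their
cohort times lognormal noise (sd 0.2); host series carry the same
measurement noise. With noise 0 and a fixed seed the output is
bit-reproducible; unstable parameter choices raise with the first
overflowing timepoint.

**Heaps oracle.** Presence matrices with a planted γ are built by
solving (non-negative least squares) for the occupancy histogram whose
*exact* expected rarefaction curve is scale·k^γ under exchangeable
random genome subsets, so the planted exponent is recovered by the
fitting procedure to ±0.05 and the check is independent of any
particular genome order.

**What passing does and does not show.** The generator plants exactly
the structure the pipeline is built to detect: substitution-only
divergence, clean gene boundaries, diagonal host–virus coupling, and
noise that is lognormal and independent across timepoints. Passing
demonstrates the statistics and thresholds behave as specified under
those conditions; it does not demonstrate robustness to assembly and
binning artefacts, strain recombination, non-uniform coverage (GC bias,
repeats), generalist viruses infecting several genomovars, or
autocorrelated measurement error. Published headline values that depend
on the real metagenomes (genome counts, vOTU counts, cohort counts, the
real-data γ) are inputs or out of reach at this scale, not reproduction
targets; under the intense-disturbance regime the Hqrw3-like genomovar's
niche is rarely realized and its cohort legitimately stays unassigned.

## Pipeline

`halovar pipeline run` executes simulate → genomovars → recruit →
pangenome → votus → lsa → cohorts on the default scenario (60 kb
ancestor, 40k reads), logging to stderr, hashing every output into
`manifest.json` (per-stage seeds derive as global seed + stage index)
and writing a text `summary.txt` with entity counts and abundance trend
slopes. Exit codes: 0 ok, 2 configuration error, 3 stage failure.
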