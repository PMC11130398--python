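# Methods

This note documents the models, parameter choices, numerical conventions,
and the scope of the synthetic-locus generator. Coordinates are 0-based,
half-open everywhere internally; GFF3 and VCF are converted at the
boundary.

## Depth normalization and the two-MAPQ-view design

Read depth is binned (default 100 bp) as read-bases per bin. The diploid
baseline *c* is the **median** per-bin per-base depth over control regions
(median, not mean, so occasional CNVs or dropouts inside the controls do
not shift the baseline; at least 10 control bins are required). Normalized
copy numbers are `2·depth/c` for the paralog-specific core regions and
`2·read-bases/(c·unit_length)` for the combined gene-body footprint, where
`unit_length` (default 8,000 bp) is the reference footprint of one paralog
unit, so a genotype with `b3 + a6` total units has expectation `b3 + a6`.

The load-bearing convention is the MAPQ split: core regions count only
reads with MAPQ ≥ 30 (uniquely placed, hence paralog-specific), while the
body is counted at MAPQ ≥ 0. Reads from the ~5 kb homology tract cannot be
assigned to a paralog, but they land *somewhere* inside the body, so the
body total — and with it `cn_sum` — is preserved even where the paralogs
are indistinguishable. Normalization uses explicit control regions rather
than genome-wide depth; for the synthetic locus these are shipped in the
generated BED, for GRCh38 they are user-supplied config entries (the
region names are known but their exact bounds are not published, so the
package does not hard-code them).

Cluster-plot coordinates are `x = cn_sum`, `y = cn_b3core/cn_a6core`; when
`cn_a6core` falls below the zero-copy threshold (default 0.3) the ratio is
replaced by the conventional placeholder `y = 4`, keeping the function
total (never NaN/∞).

Per-sample QC: the `cnv2 ratio` is the fraction of control bins whose
normalized CN lies in [1.5, 2.5]; a sample passes at ratio > 0.85. The
band definition is this package's own operationalization of a QC metric
whose published description names only the 0.85 threshold.

No GC or mappability correction is applied (the synthetic locus is
GC-neutral); a config hook (`gc_correction`) marks where one would attach.

## Joint genotyping on the lattice

Cluster centers are not estimated from data: the geometry of the problem
fixes them at `(b3, a6, b3+a6)` for integer genotypes `b3 ∈ 0..5`,
`a6 ∈ 0..7` (the upper bounds cover the known 0–6 copy range plus a
reported seven-copy individual). `LatticeMixtureCaller` fits only

* mixture weights (first pass uniform, then empirical — a two-pass prior
  that lets a handful of query samples borrow mass from a background
  cohort), and
* a per-dimension variance law `σ_d²(μ) = σ0_d² + k_d·μ`, estimated by
  responsibility-weighted least squares of squared residuals on the
  component means. When the unconstrained intercept falls below the
  variance floor (1e-6), the slope is refit through `(0, floor)` by
  constrained least squares — with most cohort mass at a single μ per
  dimension the unconstrained line is poorly determined, and the
  constrained refit keeps the fitted variance at the occupied components
  faithful. The floor is deliberately small because the sampling variance
  of normalized CNs at 30x is of order 1e-5–1e-4.

Calling is MAP over the lattice using the three-vector
`(cn_b3core, cn_a6core, cn_sum)` — never the plotted ratio, which is
unstable near zero `cn_a6core`. Components are ordered by
`(b3+a6, b3, a6)` so exact posterior ties resolve toward the smaller total
copy number, then the smaller `b3` (determinism). Fitting requires ≥ 20
observations; with fewer, include a background cohort (simulated or
reference). On noise-free lattice data the calls are exact and re-calling
with called samples appended to the background is idempotent.

## Haplotype frequencies and diplotypes

Haplotype CN types live on `h_b3 ∈ 0..2`, `h_a6 ∈ 0..4`. Frequencies are
estimated from ≥ 50 integer genotypes by a Hardy–Weinberg EM over the
diplotypes consistent with each genotype (convergence at Δloglik < 1e-8;
the log-likelihood trace is recorded and is non-decreasing). The EM
surface has symmetric local optima — several splittings can explain the
same genotype spectrum — so the fit runs a small deterministic multi-start
(a "halved genotype" seeding, a maximally skewed A6 split, and a graded
init) and keeps the best likelihood. Frequencies are floored at 1e-4 and
renormalized after convergence.

The default prior table for worked examples, `f(1,1)=0.55, f(1,2)=0.20,
f(1,0)=0.15, f(1,3)=0.05, f(0,0)=0.01`, others at the floor, encodes the
qualitative knowledge "one copy of each per haplotype is modal; the
hybrid (0,0) haplotype is rare" — no published frequency table exists.

Diplotype decomposition ranks all pairs `h₁+h₂ = g` with probability
∝ `f(h₁)f(h₂)·(2 if h₁≠h₂)`, normalized; a genotype outside the haplotype
span returns an empty list with a warning.

## Trio model

Configurations are (father diplotype, mother diplotype, transmitted
paternal pick, transmitted maternal pick); enumeration is complete over
the haplotype space. Scores multiply the Hardy–Weinberg prior of both
diplotypes, the ¼ transmission factor, and observation likelihoods:
indicators for integer-genotype inputs, Gaussian likelihoods under the
fitted caller's noise model for continuous normalized-CN inputs (the
published trio example quotes a continuous child value, so both input
kinds are supported). Parental priors default to population frequencies
with a `uniform_prior` fallback flag. No Mendelian-consistent
configuration is a hard `InconsistentTrioError` — de-novo CNVs are
deliberately not modelled, so the error is the signal to inspect the
calls. Ranking ties break on lexicographic haplotype labels.

## Long-read deletion calling

Candidates come from two channels: CIGAR D/N operations ≥ `min_del_length`
(default 50 bp) and same-chromosome, same-strand primary/supplementary
pairs adjacent in read coordinates (query gap ≤ 100 bp) with a reference
gap — candidate length is the reference gap minus any positive query gap.
Opposite-strand pairs (inversion signals) are ignored; only deletions are
called. Candidates cluster by single-linkage with both breakpoints within
`pos_tol` (50 bp; input is sorted first so clustering is
order-independent); consensus breakpoints are medians, support counts
distinct reads, and the breakpoint standard deviation is reported.
Consensus calls are left-aligned against the reference — a deletion whose
junction lies in an identity tract (the NAHR situation) is only defined up
to a shift within the tract, and the smallest-start representative is the
VCF normalization convention. Genotype comes from the VAF against reads
spanning the left breakpoint without the deletion: het in [0.2, 0.8], hom
above, filtered below; calls under `min_support` = 3 are dropped with a
log line. The defaults are conventional for HiFi-scale SV calling; the
published analysis resolved breakpoints by manual inspection, and the
left-alignment rule is this package's codified stand-in. Output is
VCF 4.2 with symbolic `<DEL>` alleles and negative SVLEN.

## Hybrid-gene interpretation

A deletion forms a hybrid gene when both breakpoints are intronic in two
distinct same-strand genes: the 5′ gene keeps its exons upstream of the
breakpoint intron, the 3′ gene its exons downstream, named
`<5′ gene>-<3′ gene suffix>` (B5 + B3 → "B5-3"). An exonic breakpoint is
truncating, not hybrid-forming (warning, no model). Transcripts are exon
concatenations in transcription order, reverse-complemented on the minus
strand; a `+3` acceptor shift starts an exon 3 nt downstream, so isoform
length differences are always multiples of 3 and the frame is preserved.

Tandem (NAGNAG) acceptors: an exon has allowed shifts {0, +3} when, on the
coding strand, the canonical AG precedes the annotated acceptor **and** a
second AG sits at exon offsets 1–2, so a legal acceptor also exists 3 nt
downstream (`...AG | nAG...`). The ITIM consensus is fixed as
`[S/I/V/L]-x-Y-x-x-[I/V/L]` (the standard immunology definition;
overlapping hits are reported). In-silico PCR matches primers exactly,
anchored on their 3′-terminal 15 nt and extended 5′-ward as far as the
template agrees — 5′ cloning tails (restriction-site tags) are thereby
ignored; products run between the 5′-most matched bases of the two
primer sites. The longest identity tract is an exact longest common
substring (leftmost-in-first-sequence tie-break), computed with
`difflib.SequenceMatcher` and cross-checked in the tests against a
quadratic dynamic program.

## The synthetic locus

`build_toy_locus` lays out, deterministically per seed: a 50 kb diploid
control segment; gene B5 (13 exons of 120 bp, 600 bp introns); paralog
units A6 and B3 (8,000 bp each; 13 exons of 102 bp, 498 bp introns); a
5 kb homology tract copied verbatim from the A6 3′ side to the B3 5′ side;
a 269 bp identity tract copied from B5 intron 12 into B3 intron 11; and
the 33,692 bp deletion joining those two introns, placed so it removes B5
exon 13, the whole A6 unit, and B3 exons 1–11, with the B3 unit ending
exactly at the deletion end so noise-free `cn_sum` is integer-exact.
Constructional guarantees:

* exon lengths are multiples of 3, so every exon is frame-neutral and the
  planted ITIM codons (three on B5 exon 13; one on B3 exon 11, three on
  B3 exons 12–13 — hence the fused protein keeps 3 of the 4 B3 ITIMs) are
  in frame in both native and fused transcripts;
* the A6/B3 exon-intron period is 600 bp on both sides and the homology
  copy is phase-aligned, so copying the tract preserves gene structure;
* exonic stop codons and tyrosines outside planted motifs are scrubbed, so
  ITIM counts on translated products are exact by construction, and
  accidental tandem acceptors are removed so exactly B5 exon 8 and B3
  exon 12 are NAGNAG;
* the flanks of both identity-tract copies are forced to mismatch, so the
  longest common substring is exactly 269 bp and the planted deletion is
  already left-aligned (the caller's left-alignment is a no-op on it);
* a ~23 kb flank follows the last gene so reads from a deletion haplotype
  can anchor beyond the junction as they would on a real chromosome.

Short-read depth is simulated at bin level: per-base counts are Poisson
with mean (depth-per-copy × copies covering the base), aggregated into
bins whose edges respect region and tract boundaries (so noise-free
expectations are exact). Homology-tract bases are ambiguous: their reads
appear only in the MAPQ-0 view, split Binomial(½) between the two paralog
positions; everything else appears in both views. An `exact=True` mode
substitutes expectations for draws (the infinite-depth limit). Long reads
(N(15,000, 3,000²) bp, 30x diploid default) are emitted directly as
alignments by projecting through the haplotype-to-reference coordinate
map; a deletion-crossing read becomes a single D-op record with
probability 0.5, otherwise a split primary/supplementary pair; segments
with < 30 bp anchor are soft-clipped away. Substitution errors
(`error_rate`, default 0) do not perturb alignments. Cohorts draw
diplotypes under Hardy–Weinberg. All randomness flows from one seeded
generator; identical seeds give byte-identical artifacts.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: real LILR sequence content (the locus is random
DNA apart from planted motifs), GC and mappability bias, indel/homopolymer
error profiles, fragment-level short-read sampling (depth is bin-level),
alignment-software artifacts at the breakpoints, and population structure
beyond Hardy–Weinberg.

## Problem sizes used by the test suite and acceptance script

Statistical checks run at: 200 samples × 30x for caller accuracy (≥ 99%
required), 1,000 genotypes for EM frequency recovery (± 0.03), one
heterozygous carrier at 30x long-read depth for deletion recovery (exact
breakpoints required). These sizes make the whole suite run in well under
a minute while leaving the statistical assertions comfortably powered.

## Known limitations

* Core/control region bounds for GRCh38 are config entries, not shipped
  annotations; results on real data depend on choosing them well.
* The cnv2 QC band is this package's own definition (only the threshold
  is published).
* The variance law is linear in copy number; baseline-estimation noise
  adds a small quadratic component that the fitted slope partially
  absorbs (harmless for MAP calling, visible when interpreting `k_`).
* De-novo CNVs in trios are rejected, not modelled.
* Only deletions are called from long reads; insertions, duplications and
  inversions are out of scope, as is local de-novo assembly.
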