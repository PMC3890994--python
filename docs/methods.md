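# Methods

This note documents the models, statistical procedures and numerical choices
behind `repsel`, and what the synthetic data does and does not establish
about real repertoire data.

## The synthetic germline reference

Real immunoglobulin germline reference sets are large, versioned and
license-encumbered; `repsel` instead generates a fully self-contained toy
reference from a seed. Allele **names** reuse the germline calls of the
bundled ELISA clone panel (11 IGHV, 7 IGHD, 6 IGHJ, 8 IGKV, 5 IGKJ, 7 IGLV,
3 IGLJ), so worked examples read naturally, but every **sequence** is random
sense-codon text with two engineered landmarks:

* each V segment ends in a Cys codon (the 2nd-CYS, "Cys-104") followed by two
  junction-spare codons that exonuclease trimming may remove
  (`anchor_pos = 3·(v_codons−3)`, default V length 88 codons = 264 nt);
* each J segment carries, after two trimmable codons, a Phe/Trp codon that
  begins a [FW]-G-X-G motif (Trp on IGH, Phe on IGK/IGL, matching the locus
  convention of real J genes; default J length 16 codons = 48 nt).

D segments are 12–18 nt. For D alleles that appear in the clone panel, the
segment embeds a codon-aligned encoding of a 3-amino-acid window from the
centre of the host clone's heavy CDR3 interior; this makes the panel's
printed CDR3s constructible over the toy reference with a recoverable ≥9-nt
exact D match. The fixture-read builder *discovers* the window by translating
the D in all frames and searching the CDR3 — nothing is hard-wired per clone.

Because alleles are independent random sequences, they are mutually
distinguishable by construction. Real alleles of one gene family differ at a
handful of positions; V-call accuracy measured here (≈100 %) is therefore an
upper bound and does not transfer to real data, where allele-level calls are
intrinsically ambiguous. CDR3 recovery is less affected by this caveat
because it depends on the anchors, not on the specific allele.

## Repertoire simulation

Clonotypes are built by V–(D)–J joining with geometric 3'/5' trimming (mean
2 nt per end, capped so both anchors survive) and uniform 0–10 nt untemplated
N-insertions on each side of the D. A configurable fraction of clones
(default 95 %, a typical productive fraction for a display library) is forced
in-frame by padding the second N-insertion to make the junction a codon
multiple, and resampled (bounded retries) if the junction contains a stop.
Somatic point mutation is applied at 0.005 per base outside the junction;
the junction itself and the three codons after the J anchor (the conserved
FR4 [FW]GXG motif) are spared, mirroring the strong conservation of these
positions in functional rearrangements. Mutations that would create an
in-frame stop are skipped so productivity is controlled by the junction
alone.

Clone abundances follow a Zipf law with exponent 1.1 (rank 1 = clone 1);
the diversity and abundance law of the real source library are unknown, so
these are stated defaults, not estimates.

**Selection** is multiplicative: after `r` rounds of biopanning on an
antigen, clone frequencies are `f'_i ∝ f_i · w_i^r` with per-clone fitness
`w_i ≥ 0` (1.0 for background clones, optionally jittered by a lognormal
with σ = 0.05; planted binders default to w = 20). Two rounds at w = 20 give
a 400-fold relative boost, which reproduces the separation of functionally
selected clones from the bulk in enrichment scatter plots. Sequential double
enrichment (LMP-1 then MBP) is the composition of two such schedules.

**Reads** are drawn multinomially from the current frequencies. Mate 1 is
the amplicon's first 250 nt, mate 2 the reverse complement of its last
250 nt (2×250 paired-end layout; amplicons of 310–370 nt leave a guaranteed
overlap window). Substitution errors are iid at 0.001 per base — a
representative figure for a high-fidelity amplicon protocol on this
platform — with uniform Q30–Q40 qualities; indel errors, chimeras and
amplification bias are deliberately out of scope. Reads are emitted grouped
by clone with sequential ids; all randomness flows from one recorded seed.

## Merging and annotation

Read pairs are merged by scanning overlap offsets for the maximal
`matches − 2·mismatches` score, requiring ≥ 20 nt overlap and ≤ 10 %
mismatches; disagreeing bases resolve to the higher-quality call (ties to
mate 1). A seeded fast path (exact 24-mers of mate 2 located in mate 1)
proposes offsets and falls back to the full scan when no seed survives.

Annotation assigns the V by best local alignment over all loci
(match +2, mismatch −3, gap open −5, extend −2; score ties break to the
lexicographically smallest allele name), then the best J downstream of the V
match, then — heavy locus only — the D by longest exact match ≥ 5 nt inside
the junction interior. Because all simulated noise is substitutional, the
optimal local alignment against the true allele is gap-free; the annotator
therefore first evaluates seed-anchored diagonals exactly (maximal-scoring
segment via a cumulative-sum scan) and only runs the affine-gap dynamic
program (Biopython's `PairwiseAligner`) when the fast path finds no
confident, anchor-covering hit. Both paths share one scoring scheme and
return the same optimum whenever that optimum is ungapped. Results are
memoized per merged sequence.

Germline identity is `100 · identities / aligned columns` over the V
alignment, internal gaps counting as mismatches; the 70 % filter threshold
is interpreted at nucleotide level (the amino-acid alternative is not
implemented) and is boundary-inclusive. CDR3 coordinates come from mapping
the germline anchor positions through the alignment; a read is productive
iff both anchors are found, the junction length is divisible by three, and
no stop codon occurs from the V start through the J anchor. Filtering keeps
productive, ≥ 70 %-identity, chain-consistent records and tallies exclusions
by reason (`unmerged`, `no_anchor`, `unproductive`, `low_v_identity`,
`chain_mismatch`); survivors plus exclusions always partition the input.

## Enrichment statistics

For a (baseline, enriched) pair the analysis unit is the CDR3 amino-acid
sequence; the point set is the union of keys, absent keys entering at
count 0. Counts are transformed with Anscombe's `2·√(count + 3/8)` on both
axes before ordinary least squares. This is a deliberate choice: the
outlier test assumes homoscedastic residuals, and for multinomial/Poisson
counts neither raw counts (variance ∝ mean) nor log1p (variance ∝ 1/mean at
large counts) stabilizes the variance — measured family-wise error rates of
the test under a no-selection null were 1.0 (raw) and 0.5–0.8 (log1p)
versus 0.07 with the Anscombe transform at the default scale. `sqrt`,
`log1p` and `identity` remain available via configuration for comparison.

Outliers are scored by **externally studentized residuals** (the point's
prediction error scaled by a leave-one-out error estimate), with two-sided
p-values from t(n−3) Bonferroni-corrected across the n points — the
standard single-outlier regression test applied per point. A point is
labelled `positive`/`negative` by residual sign when its corrected p-value
is below α (default 0.05). Numerically exact fits (identical libraries)
produce 0/0 studentized residuals; residuals below a 1e-10 relative noise
floor are treated as zero, not as outliers. The t-based test remains
slightly anticonservative for count data (Poisson right-tail skewness at
moderate counts); the measured null family-wise rate of ≈ 0.07 at the
default scale (2000 clonotypes, 50 000 reads per library, 200 seeds) is
within the documented ≤ 0.10 envelope but should not be read as exact 0.05
control. Known limitation: with many simultaneous strong binders the shared
error estimate inflates (outlier masking), reducing power at shallow read
depth; the effect vanishes at the default depth.

Polyreactivity summaries require a shared baseline (identical baseline
counts across pairs, enforced): per CDR3 they count sublibraries with
positive selection and with increased normalized frequency; a CDR3
increased in *all* provided sublibraries is flagged polyreactive, and one
positively selected in every member of a named antigen subset (e.g.
MBP ∧ LMP-1 ∧ LMP-1/MBP) is a cross-reactivity candidate.

## Charge profiling

Net charge is an integer sum per residue: K, R = +1; D, E = −1; all other
residues — including His — 0 under the default physiological-pH convention;
a His = +1 scheme is provided because the convention is not universal.
Ambiguity codes (X) contribute 0 so partially determined CDR3s remain
computable. Profiles weight each unique CDR3 by its read count (a
per-unique-CDR3 mode exists but is not the default), so bin totals equal
filtered read totals exactly — integer arithmetic throughout. Comparisons
report per-bin and aggregate fold changes of normalized frequencies
(neutral {0}; strong-negative ≤ −4; strong-positive ≥ +4; configurable);
an empty reference bin with occupied enriched bin is reported as infinite
with both frequencies attached rather than silently clipped.

## Pipeline scenario and ground truth

The default `RunConfig` emulates one initial library (2000 clonotypes per
chain, Zipf 1.1) and four sublibraries (MBP, MOG, LMP-1 at two rounds each;
LMP-1/MBP as two rounds of each sequentially) at 50 000 reads per chain per
library. Planted structure per chain: 8 antigen-specific binders per
antigen, 2 polyreactive clones (fitness 20 for all three antigens, hence
enriched in all four sublibraries), and 2 cross-reactive clones (MBP and
LMP-1, hence also the sequential library). MOG binders are drawn as the
most negatively charged eligible clones (CDR3 net charge ≤ −2, most
negative first), so MOG selection reproduces the qualitative charge-profile
signature the analysis is meant to detect: the neutral bin shrinks and the
strong-negative aggregate grows. Binders are never drawn from the top-10
abundance ranks, so the baseline is not dominated by a planted clone. All
planted identities are recorded in the run manifest.

A full default-scale run (five libraries × two chains × 50 000 reads)
completes in about a minute on one CPU; the test suite verifies that two
runs with the same seed produce byte-identical report bundles (every table
carries the seed and a configuration hash in its header, and the manifest
echoes every setting). FASTQ dumps are optional (`write_reads`) because the
reads are regenerated deterministically from the seed; the tab-separated
tables and the manifest are the reproducibility contract.

Problem sizes used by the test suite and acceptance script — 200–500 clones
and 2 500–10 000 reads for unit-level checks, 20-seed power suites, 200-seed
null calibration, and one two-pass default-scale pipeline run — were chosen
as the smallest sizes at which the measured quantities are stable.

## What passing tests do and do not show

The simulator provides exact ground truth, mutually distinguishable
germline alleles, substitution-only noise and no PCR artifacts. Passing
recovery and power tests therefore validates the *implementation* — anchor
mapping, filter logic, outlier statistics, charge accounting, determinism —
under the stated model. They do not establish annotation accuracy against
real IMGT references, robustness to indels and chimeras, or power under
real selection dynamics, all of which are narrower or harsher than the
model assumes.
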