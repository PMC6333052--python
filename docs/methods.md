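# Methods

This note documents the models, numerical choices and limitations of
`madsbox` at the level a maintainer or reviewer needs.

## Stage 1: domain judgement

**MADS (M) domain.** MIKC membership is decided by a PROSITE-syntax pattern
match. The shipped default pattern,
`M-[GA]-R-[GS]-[KR]-[ILV]-[DEQ]-[ILM]-[KR]-[KR]-[ILV]-[DE]-N.`, is authored
against the conserved N-terminal core of plant MADS domains
(`MGRGRVELKRIEN...`); it is configuration, not a claim about any particular
PROSITE entry, and can be replaced by a pattern file (one pattern per line,
`#` comments). The matcher implements leftmost-greedy, non-overlapping
scanning with backtracking inside `(n,m)` repeats — exactly the semantics of
a translation to a greedy regular expression, which the test suite uses as
an independent oracle. An `X` in the sequence matches only the `x` (any)
element unless configured otherwise. The M span is the first match extended
to a fixed `m_length` (default 57, from the conserved ~56–57 residue MADS
region), truncated at the sequence end. Multiple matches: leftmost wins (the
MADS domain is N-terminal).

**K domain.** Rather than a second PROSITE profile (generalized-profile
scoring is a much larger surface), the K domain is located by the package's
own coiled-coil engine. Candidate detection uses only the widest configured
window (28): wide windows average more positions, which suppresses the
score fluctuations of random sequence that would otherwise produce spurious
coil calls in the I/C regions. The best-scoring placement must reach
probability ≥ 0.5. Boundaries are then refined by maximal-sum extension of
per-residue log-odds `w·(ln propensity − ln pivot)` (pivot 1.2) in the
locked heptad frame; on planted-construct tests this localizes coil edges to
within ~3 residues, and on the synthetic benchmark the mean absolute
boundary error is ~1 residue. The I domain is the M–K gap when ≥
`min_i_length` (default 5); the C domain is the tail after K. `is_mikc` is
true exactly when an M span is present, so fragments lacking the M domain
(e.g. K+C) are rejected at stage 1 — the routing contract requires a
recognized MADS context.

**Coordinates** are 0-based, half-open everywhere.

## Coiled-coil scoring

A window of width w at heptad frame f scores
`exp( Σ w_p ln m(res, p) / Σ w_p )` — the weighted geometric mean of
per-residue propensities `m` with heptad-position weights a,d = 2.5 and
b,c,e,f,g = 1.0. The window score is the best frame; each residue takes the
maximum over windows covering it; a per-width two-Gaussian likelihood ratio
`P = G_cc/(G_cc + G_glob)` converts scores to probabilities, and the final
per-residue probability is the max over widths {14, 21, 28}. Sequences
shorter than the smallest width get an all-zero profile flagged `too_short`.

The propensity table and Gaussian parameters ship as TSV data files
(`data/coiled_coil_propensities.tsv`, `data/coiled_coil_gaussians.tsv`).
They are authored for this package in the structure of the MTIDK statistics
of the classic COILS method — hydrophobic residues enriched at the core a/d
positions, charged/polar residues at b,c,e,f,g, proline strongly depleted —
and calibrated so that ideal hydrophobic-a/d heptads score ≈ 1.9–2.0 and
globular sequence ≈ 0.9, with per-width Gaussian spreads shrinking as the
window grows. `X` has neutral propensity 1.0. All scoring routines are
parameterized over whatever table is loaded, and the oracle tests compare
against a naive triple-loop reimplementation on the loaded table, so
swapping in a different table does not invalidate the engine.

## Alignment statistics

Local alignment is optimal Smith–Waterman under BLOSUM62 with affine gap
costs: a gap of length L costs `open + L·extend` (defaults 11/1, the NCBI
convention). `X` scores 0 against everything. The dynamic programming runs
through Biopython's C `PairwiseAligner`; the test suite checks raw scores
against an independent recursive path-enumeration oracle on short pairs.
Bit scores use the standard gapped BLOSUM62 Karlin–Altschul parameters
λ = 0.267, K = 0.041 (configurable); e-values use a per-pair search space
m·n rather than a database-summed one, because the downstream feature is a
per-subject average — this is documented precisely because it shifts the
e-value gate relative to a database-wide search. No seeding heuristics,
composition-based statistics or HSP culling are modeled.

## Feature encoding

**Class similarity (8 values per region).** The query region is aligned
against every member of each class's region-restricted reference database;
hits with e-value < 10⁻⁵ are kept and their bit scores averaged (over
passing hits only); a class with no passing hit encodes 0. When a reference
sequence is itself being encoded (training), it is excluded from its own
class database. Averages use sorted summation so the feature is invariant
to database order.

**M-domain DNA-binding propensity (171 values).** The retired BindN
predictor's trained weights are unpublished, so this block is a documented
self-contained encoding built from the same three input scales BindN used:
per-position triplets of side-chain pKa (non-ionizable side chains set to
neutral 7.0), Kyte–Doolittle hydropathy, and residue mass, each min-max
normalized over the 20 standard residues; fixed 57-position layout,
zero-padded past the sequence end; `X` encodes the scale means.

**K-domain coiled-coil summary (3 values).** `[mean, max, fraction ≥ 0.5]`
of the per-residue coil probability over the K span.

## Classification and routing

Nine recipes: `whole-sim`, `m-sim`, `i-sim`, `k-sim`, `c-sim`, `m-bindn`,
`k-coils`, `m-sim+bindn`, `k-sim+coils`. Each is an RBF-kernel SVM
(one-vs-one, Platt-calibrated probabilities) on features min-max scaled to
[0, 1] with training-set bounds (clamped at prediction time; constant
features map to 0). Hyperparameters come from a coarse log-2 grid search
(C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, steps of 2) under stratified 3-fold CV with
a fixed seed. Predicted class is the argmax of the calibrated probabilities
with ties broken by the fixed class order (A, B12, B34, BPI, C, D, E, AGL6)
for determinism.

Routing: among models whose required regions are present in the annotation,
the one with the highest CV accuracy wins (ties by registration order). The
whole-sequence recipe requires the complete M+I+K+C content, so fragments
are always routed to domain models; its features remain computable on any
sequence, which is what the "forced whole-sequence" arm of the benchmark
exercises. Non-MIKC inputs are rejected before any feature encoding.

The standalone `cross_validate` rebuilds the reference databases per fold
from that fold's training split only — no test-fold sequence contributes to
any feature it is evaluated on. Fold accuracies use the SVM decision rule
directly (probability calibration does not change the accuracy measurement
and is substantially slower to refit per grid point).

## Conservation summaries

Uncorrected p-distance (proportion of differing comparable columns,
pairwise deletion of gap/X columns) keeps all values in [0, 1]; mean and
(population) variance are taken over all unordered pairs, and the standard
error of the mean comes from a column bootstrap (500 replicates, seeded).
A deliberately naive alignment utility projects unequal-length region sets
onto the longest sequence via pairwise global alignment; it is not a
progressive multiple aligner and alignment quality is outside the package's
guarantees — pre-aligned input is preferred.

## Synthetic data generator

The generator emulates a curated eight-class MIKC reference set with the
layout M(57) + I(30) + K(70) + C(60). From a common root, one ancestor per
class is derived with per-region "extra" substitution rates M 0.05, I 0.25,
K 0.20, C 0.40 — concentrating class-level divergence in C, then I, K, M,
the diversity ordering reported for real MADS domains — and members derive
from their ancestor at a within-class rate of 0.10. Substitutions are drawn
from a BLOSUM62-conditional kernel `P(b|a) ∝ exp(S(a,b)/2)` so that
alignment bit scores and e-value gating behave realistically. Defaults are
8 classes × 10 members with a stratified 80/20 split.

Three site groups are protected from substitution, emulating purifying
selection: the 13-residue M pattern core (guaranteeing stage-1 detection),
the hydrophobic a/d positions of the K heptads (keeping the coil signal),
and a class-specific signature 6-mer planted at C positions 10–16 (the
learnable class signal that makes the C domain the most discriminative —
by construction, mirroring what the conservation analysis finds in real
data). The generator returns ground-truth spans, ancestors and the
protected-site mask so tests can use closed-form divergence expectations.

**What passing tests do not show.** The generator has no indels, no rate
heterogeneity, no domain-length variation and a single root, so the
benchmark demonstrates the machinery (feature gating, routing, calibrated
confidence, the diversity–discriminability relation under a known
mechanism), not classification accuracy on real MADS families; real-data
accuracy depends on the user-supplied reference set.

## Problem sizes

The shipped benchmark and the acceptance script use 8 classes × 10
sequences (~217 aa each), 3-fold CV with per-fold reference rebuilds, and
200–500 bootstrap replicates — sizes chosen so a complete from-scratch run
of the pipeline finishes in minutes on one CPU while still exercising every
stage.

## Known limitations

* The e-value gate follows per-pair statistics; numbers are not comparable
  to database-wide BLAST e-values.
* K-domain boundaries are accurate to a few residues, not exact; feature
  blocks tolerate this but span-sensitive downstream uses should supply
  annotations.
* Fragments without the M domain are rejected rather than classified.
* The classifier interface is pluggable in principle (any estimator with
  `fit`/`predict_proba` fits the `TrainedModel` contract) but only the SVM
  configuration ships.
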