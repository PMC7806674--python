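# Methods

## Model and procedure

`gotransfer` implements annotation transfer as a modified k-nearest-neighbor
classifier in protein embedding space.  Unlike a standard k-NN vote, *all*
GO terms of *all* retrieved hits are transferred (not only the majority
label), and each term is scored rather than accepted/rejected: the
reliability index

    RI(p) = (1/k) · Σ_{i=1..l} 0.5 / (0.5 + d(q, n_i))

converts the distance of the l hits carrying term p into a confidence in
(0, 1].  The two assumptions behind the method are (i) that language-model
embeddings place functionally similar proteins close together even when
their sequences have diverged, and (ii) that embedding distance is a usable
proxy for transfer reliability.  Neither is assumed by the code — both are
exactly what the evaluation machinery measures.

Tie handling follows the rule that every database protein whose distance
equals the k-th smallest is considered.  Floating-point distances are
declared tied when equal within a relative tolerance of 1e−9 (absolute
1e−12 near zero); the tolerance is an implementation necessity — exact
float equality would make tie expansion depend on summation order.  Under
tie expansion the 1/k normalisation can push RI above 1 (more than k
contributing hits); RI is clamped to 1.0 and the clamp logged, preserving
the documented range.  The alternative — normalising by the expanded hit
count — would make an expanded tie *lower* every RI, which contradicts the
intent that agreement among hits raises confidence.

Defaults: k = 1; Euclidean distance (cosine available — for unit-norm
vectors the two induce the same ranking since d² = 2·d_cos); RI cut-offs
BPO 0.35, MFO 0.28, CCO 0.29.  The cut-offs were calibrated on CAFA3
targets with 1024-dimensional SeqVec embeddings and are meaningful only on
a comparable distance scale; on other embedders (including the synthetic
fixtures) the F_max sweep chooses its own operating point and the cut-offs
should be recalibrated before production filtering.

## Ontology handling

GO is a DAG in three namespaces (BPO, MFO, CCO) rooted at GO:0008150,
GO:0003674 and GO:0005575.  Propagation (the true-path rule) follows
`is_a` and `part_of` edges by default — standard GO practice — and is
restrictable to `is_a` only.  Cross-namespace `part_of` edges are not
followed, keeping every term inside a single ontology, because all
evaluation is per-namespace.  `alt_id` accessions resolve to primary ids at
parse time so downstream maps use one id per term.  Obsolete terms are kept
for lookup but excluded from propagation and prediction (annotation
releases may still reference them).  Parsing validates acyclicity of the
propagation edge set and that every live term reaches exactly one namespace
root.

## Database preparation

Records can be filtered to the eight experimental evidence codes
{EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC} (preset `"experimental"`).  GAF
rows with a `NOT` qualifier are dropped — keeping them would transfer
explicitly negated annotations.  Duplicate (protein, term) rows collapse,
retaining the strongest evidence code by a fixed precedence list
(experimental codes first, IEA last); only membership matters downstream.
Isoform suffixes on UniProt accessions are stripped by default
(configurable).  Proteins annotated only at namespace roots are dropped as
uninformative, and roots are removed from all term sets; term sets are then
closed under propagation.  Term frequencies — the naive baseline's scores —
are computed per namespace over proteins with at least one term there.

## Evaluation protocol

The sweep uses a 0.01-step threshold grid (CAFA convention; callers may
pass any grid, e.g. the exact score image for rescaling-invariance checks).
Default averaging is protein-centric: precision at threshold τ averages
over proteins with ≥1 retained prediction, recall over *all* benchmark
proteins — the "full evaluation", penalising silent queries.  A pooled
"micro" mode applying the P/R/F1 formulas to summed counts is kept for
transparency; the two coincide for a single benchmark protein.  Proteins
with empty truth in a namespace are excluded from that namespace's
benchmark (their recall is undefined).  F1 ties across thresholds resolve
toward the larger τ.  Precision is *not* asserted monotone in τ — it
genuinely fluctuates when few predictions survive high cut-offs.
Confidence intervals resample the benchmark protein set with replacement
(default 10,000 draws) and report ±1.96 bootstrap SD.  NK (no prior
experimental annotation) / LK (prior annotation in 1–2 other namespaces)
partitioning of a benchmark against an earlier database snapshot is
provided for CAFA-style mode splits.  Jaccard set similarity and Spearman
rank correlation (average-rank ties; NaN for constant inputs) support
comparisons between similarity measures.

## Synthetic worlds

The generator emulates the *cluster structure* that makes embedding-based
transfer work, not the embeddings themselves: each "function family" has a
centroid, centroids sit on random orthonormal directions scaled so every
pair is exactly `s` apart (hence `n_families ≤ D`), members are drawn from
a spherical Gaussian with spread σ, and each family owns a distinct set of
ontology leaf terms (annotated, then propagated).  The s/σ ratio is the
single difficulty knob: s ≫ σ makes 1-NN family recovery near-certain,
s = 0 makes it chance.  Label noise reassigns whole term sets of a wrong
family — mimicking transfer from a wrong homolog — rather than flipping
individual terms.  Defaults: 3 namespaces × 40 terms (depth-3 branching-3
trees with a 15 % diamond fraction), 6 families × 2 leaf terms per
namespace, 20 proteins/family, D = 32, σ = 1, s = 10, 10 queries/family;
chosen as the smallest world where transfer quality responds cleanly to
the knob while the full suite stays sub-minute.  What passing tests on
this world show: the pipeline's bookkeeping, the distance/RI machinery and
the evaluation protocol are correct, and retrieval quality degrades
monotonically with cluster overlap.  What they do not show: anything about
real language-model geometry — anisotropy, length effects, family-size
imbalance and annotation incompleteness of real databases are all absent.

A known property worth stating: at s = 0 (fully overlapping families) k=1
transfer scores *below* the naive frequency baseline by ~0.15 F_max here.
This is structural, not a defect — a single-hit transfer assigns one RI to
an entire (possibly wrong) family term set, so the threshold sweep cannot
separate its good terms from its bad ones, whereas the sweep hands the
naive baseline its optimal frequency cut-off, keeping exactly the
high-frequency shared ancestors.  Chance-level retrieval therefore tracks,
but does not match, the naive baseline under F_max.

## Numerical choices

Distances accumulate in float64 regardless of storage precision.
Zero-norm vectors are rejected for cosine distance rather than mapped to a
conventional value.  F1 is defined 0 where P + R = 0; two empty sets have
Jaccard similarity 1 (logged).  Hit ordering is (distance, id), making
prediction files byte-identical across reruns.  The prediction writer
rounds to 2 decimals (CAFA style) but evaluation operates on full
precision; file-based round-trip evaluation should use the writer's
full-precision mode.

## Limitations

BLAST-style sequence baselines, redundancy reduction at sequence-identity
thresholds, and language-model inference are outside the package; the
embedding store accepts whatever dimension the user's embedder produced.
Approximate nearest-neighbor indexing is deliberately absent — a single
vectorised distance pass is linear in database size and sufficient at the
intended scales.  Combining reliabilities across embedders or with
sequence scores is not supported.
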