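# Methods

## Problem setting

`rgenekit` classifies protein sequences into R-gene (resistance/defense
proteins: antimicrobial peptides, MHC, immunoglobulins, interferons,
lectins, ...) versus non-R-gene. The model is descriptor-based: no alignment
to known R-genes is required at prediction time, so novel or divergent
defense proteins remain detectable. The pipeline is the standard screening
design for this problem class: redundancy-reduced positive and negative
corpora, fixed-length physicochemical descriptors, class balancing, a
random-forest classifier, and confusion-matrix metrics under hold-out and
10-fold cross-validation.

## 188-D CTD descriptor

Each of 8 physicochemical properties partitions the 20 amino acids into 3
groups. The partition tables are the canonical ones from the CTD descriptor
literature (Dubchak-style groupings, as used by SVM-Prot-family servers) and
ship as `data/ctd_partitions.tsv`; the table is an interface, so alternative
groupings can be dropped in and validated. The published worked example we
validate against (PSBA1, the photosystem-II D1 protein of *Acaryochloris
marina*, L = 363) fixes the choice: its printed amino-acid-composition row
determines the residue counts exactly, and the canonical hydrophobicity
partition reproduces the printed composition triple (15.7025, 45.7300,
38.5675) to 4 decimals. One quirk in that published table: the row labeled
"van der Waals volume" carries a composition triple (41.3223, 39.1185,
19.5592) that matches the canonical *polarity* partition applied to the same
counts, not any vdW grouping — an apparent row-label mix-up in the source
table. We keep the canonical tables unchanged and validate the polarity
triple against that row rather than adjusting a partition to fit a label.

Numerical conventions, chosen where published CTD implementations differ:

- Distribution quantile index q = max(1, ceil(f · n_j)) for
  f ∈ {0, .25, .5, .75, 1}: monotone in f, and a single occurrence fills all
  five slots. Empty group → five zeros.
- Transitions are unordered pairs in the fixed order (1,2), (1,3), (2,3)
  with denominator L − 1; a length-1 sequence reports zeros (logged).
- All components on the percent scale (0–100), matching how such feature
  tables are printed.
- Block order: AAC, then the 8 properties in the registry order given above,
  each block C(3), T(3), D(15, group-major).

Wildcard residues (`X`, the sanitized form of B/J/O/U/Z/`*`/gaps) belong to
no group and no composition count, but denominators keep the full length L:
a sequence with 10% unknown residues is not silently renormalized into a
cleaner-looking one.

## Pse-AAC

Type-I (series-correlation) pseudo amino acid composition with λ = 10,
ω = 0.05 and three property scales (hydrophobicity, hydrophilicity,
side-chain mass), each standardized to zero mean and unit population
variance over the 20 residues before use — unstandardized scales would make
the correlation function Θ unit-dependent. The defaults give the 30-D
vector used in the comparison experiments; λ, ω and the scale set are
exposed in `PseaacConfig` (an amphiphilic type-II variant would have
dimension 20 + 2λ and is out of scope beyond this config hook). λ = 0
reduces exactly to normalized composition; the vector always sums to 1 by
construction.

## Redundancy removal

Greedy incremental clustering with the identity definition CD-HIT uses:
identical matches in a global alignment divided by the shorter length.
The alignment maximizes matches with match = 1, mismatch = 0, linear gap
penalty −1. Sequences are processed longest first (ties broken by id) so
results are deterministic; no k-mer prefilter is applied — at desk scale the
O(n · clusters · L²) all-pairs-to-representative cost is acceptable. The
greedy scheme guarantees each removed sequence is ≥ threshold to its
representative but not that all representative pairs fall below the
threshold; the family-recovery tests verify cross-representative identities
directly.

## Class balancing

`under_sample` down-samples the majority class uniformly without replacement
to the minority size; leftover majority instances form the hold-out. At the
study-scale corpus sizes (6720 positives, 10028 negatives) this yields a
6720/6720 training set and a 3308-negative hold-out, and because the
hold-out is all-negative, its "accuracy" is simply the specificity at
threshold 0.5 — SN is reported as NaN with a warning rather than silently 0.

`weighted_sample` interprets "adding weights" as per-instance weights
consumed by weight-aware learners (WEKA-style instance-weight semantics).
Modes: explicit mapping; `"paper"` = 10 (minority) / 7 (majority), which at
a ≈7:10 class ratio makes the total class masses near-equal
(67,200 vs 70,196); auto = inverse class frequency normalized to mean 1.

## Classifier and evaluation

Random forest with 100 trees, √p features per split, unlimited depth,
seedable — common defaults for this descriptor dimensionality; hyper-
parameters are exposed through `LearnerSpec`, and SVM, naive Bayes, k-NN,
bagging, AdaBoost and gradient boosting are reachable through the same
interface for comparison studies (scikit-learn implementations throughout).

Cross-validation is stratified, and fold predictions are pooled into a
single confusion matrix before scoring, producing one SN/SP/Acc/MCC/ROC
value per run rather than fold means — with balanced classes this makes
Acc = 100(SN + SP)/2 an exact identity. ROC area is computed as the rank
statistic (Mann-Whitney form, ties counted half), which equals trapezoidal
integration of the ROC curve. Undefined metrics (an empty class) are NaN
with a warning, except MCC → 0, an explicit logged convention.

## Synthetic data: what it emulates, what it does not

Sequences are i.i.d. draws from class emission distributions; lengths are
log-normal (median 250, σ = 0.4 on the log scale) clipped to [50, 1000],
a plausible protein-length range. The positive class shifts probability
mass `effect` from residues outside a designated subset (default DEHKR, the
charged residues plus histidine) onto the subset, proportionally on both
sides, so the total-variation distance between class distributions equals
`effect` exactly; `effect` ≤ the base mass outside the subset, and the
disjoint-alphabet extreme (effect = 1) requires a base distribution with no
subset mass. A separate generator emits families of mutated near-duplicates
(per-site substitution at a configured rate) for the clustering stage.

i.i.d. emission carries compositional signal only — no motifs, domains or
phylogenetic correlation — so passing tests demonstrate that the pipeline
recovers compositional class differences and that every computational step
is correct; they do not certify accuracy on real R-gene corpora, where
signal is weaker and structured. Study conditions used by the verification
suite: effect 0.5 at n = 400 (strong signal, CV accuracy must exceed 90%)
and effect 0 at n = 1000 (null; CV accuracy must stay inside the binomial
3σ band [45%, 55%]).

## Known limitations

- Greedy clustering is order-dependent by design (longest-first) and does
  not reproduce any particular CD-HIT version's exact memberships.
- Headline accuracies on the real UniProt/Pfam corpora are not reproducible
  here: the corpora, sampling seeds and WEKA versions behind them are not
  available, which is why verification rests on arithmetic identities,
  worked-example reproduction, brute-force oracles and synthetic parameter
  recovery.
- The worked-example validation covers the order-free descriptor blocks
  (AAC and compositions); transition/distribution entries require the real
  residue order, which the printed composition does not determine.
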