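# Methods

## Interolog transfer model

Interaction networks are undirected graphs G = (P, I) over a species'
proteins, with per-edge interaction type (physical / genetic / other),
source database and PubMed evidence.  Given an ortholog mapping between a
source and a target species — a set of scored gene pairs, n:m relations and
multiple listing databases allowed — the *direct transferred network*
contains one transfer **instance** per combination of a source edge
(s1, s2) and ortholog records s1→t1, s2→t2 with t1 ≠ t2.  Instances keep
full provenance (the source edge and the two ortholog records); the same
target pair may be reached repeatedly with different provenance, and only
when a final network is materialised are instances collapsed to one edge
per canonical pair, retaining the maximum score (the best available
evidence for that pair).

Labels come from comparing instances with the target species' experimental
(gold) network under three settings: **AllI** keeps every instance and calls
it consistent iff the target pair occurs in the gold network with any type;
**PhyI** / **GenI** first restrict instances to physical / genetic source
edges and additionally require type agreement in the gold network.  PhyI,
GenI and the untyped remainder partition the AllI instance set.

Canonicalisation conventions: edges are stored once under lexicographic
order of protein ids; self-interactions are rejected on input and never
produced by transfer (neighborhood formulas are degenerate for loops).
Identifiers are matched exactly — there is no fuzzy ID-mapping layer.

## Features

Twenty feature types are modeled across the pairings source pair (S),
target pair (T) and the two ortholog pairs (O1, O2); the full set expands
to 43 columns.  Named subsets: *network* (neighborhood overlap, neighbor GO
similarity), *go* (global + per-category Resnik similarity), *general*
(source database, PubMed edge support, source type, total support,
expression correlation), *ortholog* (sequence identity, token/domain
similarity, pathway co-membership, ortholog source/score/support,
transitive orthology, phylogenetic distance).  *reduced* is *full* minus
the two network features and expression correlation — the features that
require a populated target network, hence unavailable in real prediction
filtering; *full* requires the target network and is the evaluation set.

Numerical conventions that matter:

* **Resnik information content** uses the natural logarithm; the base only
  rescales IC, leaving rankings and forest splits unchanged.  Counts use
  set semantics under upward propagation — a protein increments each
  ancestor once even across diamond paths.  Term similarity is the maximum
  IC over common ancestors (MICA).  A pooled "global" table puts a virtual
  super-root above the three category roots, so cross-category pairs score
  0 rather than being skipped.  Terms with zero annotation count have
  undefined IC and are excluded from similarity rather than treated as
  infinitely informative.
* **Missing values.** A feature that cannot be computed (no annotation,
  empty neighborhood, 0/0 Jaccard, absent expression or constant vector,
  any missing ortholog-score component) is a missing marker, never a
  silent 0 — absence of evidence is not evidence of dissimilarity.
* **Neighbor GO similarity** averages over the computable neighbor pairs
  only; if no pair is computable the feature is missing.
* **Ortholog score** combines the InParanoid-style inparalog and bootstrap
  scores of the pair's two genes as (i_s·b_s + i_t·b_t)/2; the exact
  combination is a design choice isolated behind one function.
* **Token similarity** is the Jaccard index of prepared description-token
  sets.  The preparation pipeline (lowercase, split on non-alphanumerics,
  stop-word and 1-letter removal, light rule-based suffix stemming, removal
  of tokens present in >10% of proteins as too generic) is provided for raw
  descriptions; the annotation input format carries already-prepared sets.
  The 10% generic-word cut is configurable.
* **Transitive orthology** walks the species tree: for each inner node on
  the source→target path, its closest leaf (fewest edges) other than the
  two endpoint species is collected (ties broken lexicographically for
  determinism), deduped preserving order; the feature is true iff a chain
  of pairwise ortholog records connects the source gene to the target gene
  through those species in order.  A hop with no record breaks the chain.
  Excluding the endpoints from the closest-leaf search (rather than
  dropping them afterwards) is required for the intended behaviour on
  balanced trees, where the endpoint would otherwise win the tie.
* **Total support** counts the distinct *other* source species from which
  the same target pair is transferred; the source species identifies the
  network.
* Categorical features (source database, ortholog database, source type)
  pass through verbatim; tokens unseen at scoring time map to a reserved
  `__other__` category.

## The Random-Forest-Filter

`RandomForestFilter` is a model object over a feature matrix and
consistency labels; `fit()` returns a results object carrying the trained
forest (scikit-learn RandomForestClassifier), the preprocessing statistics
and diagnostics (out-of-bag accuracy, feature importances, a `summary()`
table).  Scores are the forest's mean leaf probability for the consistent
class, in [0, 1].

Preprocessing: numeric features are imputed with the training median,
categorical with the mode, and every feature with any missing training
value gains a binary missing-indicator column — missingness is often
informative (unannotated proteins transfer worse) and imputation alone
would erase it.  Categoricals are one-hot encoded with an `__other__`
column for unseen tokens.

Hyperparameters: number of trees and per-split feature subsample, selected
by grid search maximising mean cross-validated AUPRC (default grid
n_trees ∈ {50, 100, 250, 500}, m ∈ {√d, ⌊log₂ d⌋+1, d/3}; ties break toward
the smaller model).  Defaults outside the grid search are 100 trees and √d,
which on the synthetic worlds sit within noise of the grid optimum at a
fraction of the cost.  All fits are deterministic given the seed.

Cross-validation uses plain stratified instance-level folds (10 by
default).  Protein- or pair-overlap between folds is deliberately **not**
controlled; this is a documented limitation of the evaluation protocol (see
"What the synthetic worlds do and do not show").

Threshold selection: either the smallest threshold whose cross-validated
precision reaches a target, or the threshold retaining a requested count.
Two conventional operating points are exposed in the CLI: 0.5 for
evaluation narratives and 0.18 for production-style filtering.

In production use, three filters are trained (AllI / PhyI / GenI) and
instances are dispatched by source interaction type; with no gold target
network all (T) network features are missing and the reduced set is the
natural choice.

## Evaluation

At each distinct score threshold s: precision = TP(≥s)/(TP+FP)(≥s);
**relative recall** = TP(≥s) divided by the number of consistent instances
under the unfiltered direct transfer, so threshold 0 gives exactly the
direct-transfer consistency and relative recall 1.0; regular recall
(against the gold network size) is reported when available.  Relative
recall is the primary recall axis — it measures what filtering loses, not
what the ortholog catalogue never offered.

AUPRC uses Davis–Goadrich interpolation: between consecutive achievable
(TP, FP) points, FP is linear in TP, precision along a segment is
t/((1+m)t + k), and the area is the exact closed-form integral
t/a − (k/a²)ln(at + k) summed over segments (the curve starts at
(TP, FP) = (0, 0), extending the first point's precision to recall 0).
AUROC is the rank-sum statistic with ties averaged.

Information Gain of a feature is the entropy reduction (base 2, so a pure
binary split is exactly 1 bit) of the consistent/inconsistent labeling
under partitioning by feature value.  Continuous features are discretised
into equal-frequency bins (default 10) computed on non-missing values —
robust to the heavy skew of similarity features — and the missing marker
forms its own cell, again because missingness is informative.  Ortholog
features can be reported averaged over O1/O2.

## Synthetic worlds

The generator builds complete multi-species worlds: gene families laid out
along a species tree, module structure (families grouped into functional
modules that shape both network topology and annotations), scored n:m
ortholog clusters, a three-category GO DAG (module-level process and
compartment terms, family-level function terms), tokens/domains/pathways,
module-level latent expression profiles, and a target gold network.

**Conservation is planted per target family pair** (per interolog): each
transferable pair is conserved with probability c, and a conserved pair is
written into the gold network for *every* ortholog combination reaching
it.  Planting per source edge instead would make consistency depend on how
many species transfer a pair (the gold network is shared), so measured
precision would drift above c and zero-signal worlds would not be null.
With pair-level planting, direct-transfer precision equals c exactly at
c ∈ {0, 1} and is binomial around c otherwise.  Hard negatives can be
added by rewiring a fraction of non-conserved pairs into gold with one
endpoint swapped; background edges keep every target protein connected so
that network-feature missingness is symmetric across classes.

`feature_signal` sets, per feature block, how strongly conservation shows
in the features, through two latent variables: a per-family quality (tied
to ortholog scores, coverage, annotation fidelity and token/domain
retention) and module co-membership (tied to conservation probability,
shared GO terms, pathways and expression profiles).  At signal 0 every
feature is generated identically for conserved and non-conserved pairs.

Named fixtures: `tiny` (one source species, 10 genes, full 1:1 coverage —
hand-checkable), `signal` (three sources, c = 0.3, strong GO/network
signal, moderate ortholog signal, ≈2,800 instances) and `noise` (zero
signal, c = 0.25, ≈2,000 instances).  The noise world uses a single source
species, 1:1 clusters and a single ortholog database so that every
cross-validation instance is a unique target pair: with duplicated
near-identical instances of one pair split across folds, a forest
memorises pair fingerprints and scores far above chance even with zero
feature signal.  That memorisation is exactly the fold-overlap leakage the
instance-level CV protocol does not control, so the null world is shaped
to exclude it; the signal world intentionally keeps realistic multiplicity
(multiple databases, paralog combinations, several source species), and
its measured performance therefore includes whatever advantage that
protocol grants.

**What passing synthetic tests shows — and does not.**  The worlds
reproduce the statistical skeleton of the real task: a controllable base
consistency rate, n:m ortholog clusters with InParanoid-style scores,
informative-when-present annotations with realistic missingness, module
structure in networks and function.  They do not emulate evolutionary
dynamics (duplication–divergence), realistic degree distributions,
database-specific biases, or annotations that were themselves inferred by
homology (a circularity the real data has).  Recovery results on these
worlds validate the machinery — transfer bookkeeping, feature computation,
forest protocol, evaluation identities — not the real-data performance
level.

Problem sizes used throughout testing and the acceptance script (signal
world ≈2,800 instances, noise ≈2,000, conservation-recovery worlds 2,200
transferable edges, 10-fold CV with 100 trees) were chosen so the whole
suite evaluates in about a minute while keeping binomial error on measured
rates below a percentage point; all generation and fitting is deterministic
given the seed.

## Known limitations

* Instance-level CV folds share proteins, ortholog pairs and (via
  multiplicity) target pairs between train and test; reported CV
  performance is optimistic to that extent.
* Only binary interactions are modeled; complex expansion is out of scope.
* Identifiers are exact-match; real pipelines need an ID-mapping layer.
* Transfer is single-hop; no chaining through a third species (the
  transitive-orthology *feature* inspects chains but transfer does not).
* The forest is uncalibrated: scores order instances reliably but are not
  probabilities of conservation.
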