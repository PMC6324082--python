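# Methods

## Scope and model

`translokit` scores proteins for translocation propensity between
subcellular compartments.  The scorer is linear in binary features: a
protein's raw Translocation Evidence Score (TES) is Σᵢ wᵢxᵢ over a packaged
table of 19 features — 15 Gene Ontology term indicators evaluated on
ancestor-closed annotation sets, two "degree below t" cuts (t = 14.5, 62.5)
and two "bridgeness below t" cuts (t = 2.5·10⁻⁶, 2.92·10⁻⁴) on interactome
topology.  Raw scores are min–max normalized over the scored cohort and
partitioned at 0.4487 (non/low boundary, the F1-optimal threshold on the
training cohort) and 0.6167 (low/high boundary, the maximum score of any
negative-set protein).  Both boundary points belong to the low-confidence
class: "higher than 0.6167" and "lower than 0.4487" are read as strict.

Two weight tables ship.  The default ("high") uses the three coefficients
published at 3-decimal precision (2.675 for GO:0009887, 1.353 for
GO:0005737, −0.497 for degree < 62.5) and 2-decimal values elsewhere; the
"table" variant is uniformly 2-decimal.  The high-precision table
reproduces the worked scoring example exactly (3.531).

## Featurization semantics

* **GO terms.**  Annotation sets are closed under the `is_a` and `part_of`
  relations only; other relations (e.g. `regulates`) are not conventional
  propagation relations and are ignored (configurable).  `alt_id` aliases
  are canonicalized before closure.  Obsolete terms are dropped from
  closures with a logged warning rather than an error, so stale annotation
  files still score.  Namespaces are not segregated: the model's features
  span all three GO namespaces.
* **Degree** is the number of distinct neighbours in the interaction
  network; self-loops and duplicate edges are dropped at ingest.
* **Bridgeness** is defined only on the giant component of the network.
  For proteins outside it — or with unknown topology — the bridgeness (and
  degree) indicators evaluate **false**; this "undefined ⇒ inactive" rule is
  what makes the worked example's silent omission of bridgeness terms come
  out right.
* Both degree cuts are cumulative: degree 10 activates `degree<14.5` and
  `degree<62.5`.

## Bridgeness surrogate

The published bridgeness values were computed with an external
overlapping-module detector whose numeric scale this package does not
reproduce.  Here, bridgeness is an overlapping-membership concentration
score: communities are detected on the giant component (default: greedy
modularity maximization, which is deterministic; seeded asynchronous label
propagation is available via `method="label_propagation"`), each node
receives a membership distribution p(m|node) proportional to its link count
into module m (counting the node itself once in its home module), and

    bridgeness(node) = 1 − Σₘ p(m|node)² ∈ [0, 1).

A module-internal node scores 0; a cut vertex splitting its links between
two modules scores ≈ ½.  Orderings (who bridges) are meaningful; absolute
values are not on the external detector's scale, so the packaged
bridgeness-cut thresholds apply to externally supplied bridgeness columns,
and internally computed bridgeness requires recalibrated cuts.  Greedy
modularity was preferred over label propagation as the default because it
is deterministic and does not collapse small benchmark graphs (e.g. a
barbell) into a single community.

## Training protocol

The reference learner is an in-package gradient-boosted ensemble of
decision stumps (depth-1 trees) under the logistic loss, using exact greedy
second-order split search (gain = G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)).
Defaults: learning rate 0.3, up to 100 rounds, λ = 1, candidate splits at
midpoints of observed values (quantile-thinned to ≤ 32 per continuous
feature).  Boosting stops early when no split clears `min_split_gain`
(default 12.0, in gain units): this is the regularizer that keeps
pure-noise features out of small-cohort models — on label-shuffled cohorts
the ensemble is typically empty.  The search is deterministic; ties break
by feature order.  An adapter to the `xgboost` engine (depth-1,
same rate/rounds) exists for parity cross-checks only.

Per-feature **importance** is the signed sum over stumps of
(right-leaf − left-leaf), i.e. the aggregate leaf-score contribution of the
feature being "high"/true; summation over repeated appearances of a feature
is assumed.  Feature selection keeps features with |importance| strictly
greater than the cutoff (default 0.02).

**Cross-validation** is stratified k-fold (default 5), re-randomized each
repeat (default 100) from a spawned seed sequence; stratification
guarantees both classes in every fold at the ~300-protein cohort size.  Per
repeat, held-out predictions are pooled into one ROC AUC (default); a
per-fold-average mode is also implemented since published protocols are
ambiguous between the two.  Precision–recall and Matthews-correlation
curves are recorded per repeat.

**Threshold calibration.**  The lower boundary maximizes F1 under the rule
"positive iff score ≥ t" over the sorted distinct observed scores (a rank
statistic, invariant under monotone transforms); ties resolve to the
smallest optimal threshold — observed-score candidates are used because the
published boundary value is itself an attained score.  The upper boundary
is simply the maximum negative-set score.

## Data Complexity Score

DCS(entry) = Σ_f w_f·present(f) / Σ_f w_f over weighted curated fields,
in [0, 1].  The exact published per-field weights are not available in the
main text, so weights are an editable configuration with documented
defaults: translocation-mechanism fields (mechanism, detection method,
structural information) weigh 2, descriptive fields (literature, partners,
functions, disease, pathways) weigh 1.  A list-valued field counts as
present iff non-empty — no partial credit by list length (simplest reading,
configurable by supplying custom weights over different fields).

## Synthetic data

The generators emulate the study conditions, not real biology:

* **Cohort sizes** default to 160 positives / 139 negatives (the curated
  training cohorts) inside a 400-protein network; the registry generator
  defaults to 213 translocating entries with 53 pathology-only flags and
  139 negative-category entries.
* **Interactome**: two dense blocks with 90% within-block partner sampling,
  Chung–Lu-style degree targets (base mean degree 8), positives elevated by
  `degree_effect` (default 2, mirroring the observed hub character of
  translocating proteins), and three designated bridge nodes sampling
  partners across blocks at double rate.
* **Annotations**: informative GO terms are annotated at rate 0.15 +
  `informative_effect` (default 0.6) in positives vs 0.15 in negatives;
  noise terms at 0.15 in both.  Setting both effects to their null values
  (`informative_effect=0`, `degree_effect=1`) gives a genuine negative
  control on which cross-validated AUC is ≈ 0.5.
* **Ontology**: per-namespace rooted random DAGs whose first terms form a
  backbone (root chains plus random 1–2-parent attachments); the planted
  informative and noise terms are dedicated leaves.  Informative leaves
  attach directly beneath a namespace root so that ancestor closure adds
  only the (near-constant) root column — otherwise closure creates
  saturated or strongly correlated proxy columns and planted-signal
  recovery becomes unidentifiable.  This is a deliberate idealization: real
  GO annotation does create correlated ancestor features, and the package's
  recovery guarantees do not extend to such collinear regimes.
* All generators draw from named, independently spawned RNG streams of one
  integer seed; outputs are byte-identical across runs and platforms.

What passing tests on these fixtures show: the pipeline's mechanics
(closure, topology, scoring, calibration) and the learner's ability to
recover planted, largely independent signals at realistic cohort sizes.
What they do not show: performance on real GO/interactome snapshots, whose
feature correlations, annotation biases and degree distributions are not
modelled.

## Numerical choices and degenerate inputs

* Min–max normalization of a constant cohort raises a degenerate-cohort
  error rather than emitting 0.  A frozen `(min, max)` reference may be
  supplied to score new proteins against a fixed cohort's scale.
* Scores are rendered at 4 decimals in CSV/TSV output (display convention
  of the published score listings); optional columns keep full precision.
  CSV is RFC 4180, UTF-8, LF.
* Giant-component ties break toward the component containing the
  lexicographically smallest node id.
* The OBO reader validates stanza structure (errors name the line) and
  rejects `is_a`/`part_of` cycles at load time.
* Cohort feature matrices treat undefined topology values as 0 during
  training (the indicator-false convention carried into the learner).

## Problem sizes in tests

The default verification suite uses cohorts of 299–500 proteins,
interactomes of 300–600 nodes, ontologies of ≤ 100 terms, 20-seed recovery
replicates and 100-repeat cross-validation runs — sizes at which every
planted property is comfortably detectable and the full suite runs in well
under a minute of compute per heavy test.

## Known limitations

* Bridgeness values are surrogate-scaled; published bridgeness cutoffs only
  apply to externally computed bridgeness columns.
* The packaged weight table is fixed to the published 19-feature model;
  retraining on new cohorts produces stump ensembles and importances but no
  automated conversion into a scoring weight table.
* Normalized TES is cohort-relative and ordinal ("proportional to
  translocation probability"), not a calibrated probability.
* Evidence-code filtering of GO annotations and weighted/directed
  interactomes are out of scope.
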