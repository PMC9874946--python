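# Methods

## Problem and pipeline

`phenet` stratifies a deep-phenotyped cohort into candidate clinical subtypes
from accumulated signs and symptoms.  The input is a long-format table of
ontology-coded observations (subject, term).  The pipeline is:

1. **Subsumption.**  Each term is replaced by its superclass from a flat
   term→superclass table; (subject, term) pairs are deduplicated first, since
   a cumulative record marks a sign as present or absent — a count above 1 in
   a superclass can only come from distinct terms.  Unmapped terms are a hard
   error by default (`unmapped_policy="skip"` drops and logs them; silent
   loss is worse than a loud failure).  Subjects whose rows are all zero
   (normal examinations) are removed and reported.
2. **Normalization.**  Per-column min–max scaling onto [0, 1]:
   v = (x − min)/(max − min).  Counts differ by an order of magnitude across
   superclasses, and span-normalization stops the largest classes from
   dominating every distance.  A constant column maps to all zeros (logged):
   a feature without variation carries no subtyping signal, and zero keeps it
   out of cosine numerators.  The transform is idempotent on its own output.
3. **Distances.**  Cosine distance d = 1 − u·v/(‖u‖‖v‖) between normalized
   feature vectors is the default; Euclidean and correlation (1 − Pearson r)
   distances are available behind the same interface but are not used
   downstream.  Zero vectors are a hard error (impossible after empty-subject
   filtering).  Cosine values below 1e-12 are snapped to exactly 0 so that
   parallel vectors are recognized at the threshold-0 boundary.
4. **Graphs.**  Bipartite: edge (subject, superclass) with weight equal to
   the normalized score; zero cells produce no edge, because a zero-weight
   edge is indistinguishable from no edge in weighted modularity.  Unipartite:
   edge (i, j) iff d(i, j) ≤ threshold (inclusive; default 0.4), with weight
   1 − d so that larger weight means more alike.  Isolated nodes are retained
   and surface downstream as singleton communities rather than being
   pre-filtered.
5. **Community detection.**  Weighted modularity with the resolution γ
   multiplying the configuration-model null term:
   Q(γ) = (1/2m) Σ_ij [A_ij − γ k_i k_j/(2m)] δ(c_i, c_j).  Louvain
   optimization alternates seeded-shuffle local moves with graph aggregation
   (self-loops carry intra-community weight; a self-loop contributes twice to
   the weighted degree).  Move ties break toward the incumbent community,
   then the lowest community id; a move must improve the gain by more than
   1e-12.  The sweep order is re-shuffled each phase from a single seed, so a
   fixed (graph, γ, seed) is exactly reproducible, and modularity after each
   phase is recorded and non-decreasing.  Defaults: γ = 1.0 for the
   unipartite graph, 1.15 for the bipartite graph.  Bipartite graphs are
   partitioned as plain weighted graphs (subject and feature nodes may share
   a community).  Communities of one node are dropped post hoc and reported;
   survivors are renumbered 1..K by descending size (ties by smallest member
   id) for stable labels across runs.
6. **Characterization.**  Per-community feature means; names from the one or
   two highest-mean features (runner-up appended when its mean is
   ≥ `second_feature_ratio` × the top mean, default 0.8; exact ties break
   lexicographically; all-zero means yield "indeterminate").  Per-feature
   one-way fixed-effects ANOVA across communities,
   F = [SSB/(K−1)]/[SSW/(N−K)], p from the F(K−1, N−K) distribution; zero
   within-group variance with nonzero between gives F = +inf with the
   smallest positive p (logged).  Raw p-values are reported across the 16
   features; a Holm step-down adjustment is available behind a flag as an
   explicitly labelled extension.  ANOVA and profiles use the normalized
   matrix (the partitions were computed on normalized data); the raw-count
   matrix can be profiled as well.  Cross-partition concordance is the full
   Jaccard matrix J = |A∩B|/|A∪B| over community member sets (restricted to
   subjects retained in both partitions), with a greedy descending-J best
   match — transparent and auditable against the full matrix, rather than an
   optimal assignment.
7. **Feature maps.**  Heat-map leaf orders by agglomerative clustering: rows
   on Euclidean distance, columns on correlation distance, Ward linkage.  A
   zero-variance column has no defined correlation and is assigned the
   maximal distance (2.0) to every other column, with a warning.

An exhaustive Bell-number enumeration over all set partitions
(`brute_force_best_partition`, ≤ 10 nodes) provides the exact
maximum-modularity oracle used throughout the tests; ties prefer fewer
communities, then the lexicographically smallest canonical labelling.

## Synthetic cohorts

The generator emulates the statistical shape of a real RRMS deep-phenotyping
cohort, since no such cohort is publicly deposited:

* **n_subjects = 113** after exclusions;
* **vocabulary**: the packaged synthetic 244-term map under the 16 canonical
  superclasses — 16 terms for each of the four classes that dominate such
  cohorts (weakness, sensory, hyperreflexia, incoordination), 15 elsewhere.
  The map is a constructed stand-in, config-replaceable, and never presented
  as a published table;
* **per-subject totals** T ~ NegBin with mean μ = 13.2 and SD σ = 9.2,
  parameterized by (n, p) = (μ²/(σ²−μ), μ/σ²).  A Poisson cannot produce an
  SD of 9.2 at mean 13.2, so overdispersion is required (σ² > μ is
  validated);
* **subtypes**: five by default — fatigue, pain, cognitive, sensory,
  gait/weakness/hypertonia — drawn with uniform mixing.  Each subtype's
  superclass signature θ_k is uniform over its signature classes and zero
  elsewhere, so at signal s = 1 a subject's observations are confined to its
  subtype's classes exactly;
* **signal strength s ∈ [0, 1]**: superclass allocation is
  Multinomial(T, (1−s)·uniform + s·θ_z).  s = 0 is the structureless null;
  the default s = 0.9 is the high-signal condition;
* **terms**: within each superclass, distinct terms are drawn without
  replacement from that class's vocabulary, capped at the vocabulary size —
  generating at the term level exercises the subsumption stage end to end.

All randomness flows from one seed through named per-stage substreams
(subtype, total, allocation, terms), so cohorts are byte-reproducible.

Two deliberate consequences of this design are worth knowing.  First,
distinct-term capping can only lower the realized mean total below the
negative-binomial mean; with point-mass signatures a large draw concentrates
on one class of ~15 terms, so the realized mean sits roughly 10–15% below
13.2 and the upper tail (hence the SD) is compressed.  Second, at s = 0.9 the
nine superclasses outside every signature receive only the 10% uniform
background (≈ 0.08 symptoms per subject per class), so their cohort-wide
column maxima are 1–2.  Per-column min–max scaling then amplifies a single
shared background symptom to a full-scale feature value, which creates
spurious strong cosine similarities between subjects of different subtypes
and typically fragments the thresholded graph into 5–8 communities instead
of a clean 5 (adjusted Rand index ≈ 0.7 rather than ≈ 1).  The same pipeline
run on raw counts recovers the five planted subtypes essentially perfectly,
which isolates the effect to the normalize→cosine interaction with
near-empty columns — a real phenomenon of span-normalizing sparse count
features, retained rather than patched because both the mixture formula and
the normalized-distance pipeline are the package's defined method.  Real
cohorts of this kind do not have near-empty superclass columns (all 16
classes carry substantial counts), so passing or failing at high signal on
synthetic data speaks to this sparse-background regime, not directly to real
data.

Other aspects of real data the generator does not emulate: longitudinal
visit structure, relapse dynamics, demographic covariates, correlated
co-occurrence of classes (e.g., weakness with hyperreflexia) beyond what the
signatures impose, and any term-frequency skew within a class.

## Problem sizes and numerical choices

The test and acceptance workloads are sized for quick, deterministic runs:
50 random graphs for the analytic modularity identity; 200 random weighted
graphs of 4–8 nodes against the exhaustive oracle (Bell(8) = 4140 partitions
each); a 4 × 8 planted-partition SBM; study-scale cohorts (n = 113) for
end-to-end recovery, with 20 null seeds and 10 seeds per signal level for the
monotonicity check.  Modularity is accumulated per community as
Σ_c [L_c/m − γ(D_c/2m)²], which reproduces the double-sum definition to
better than 1e-12 and is exactly 0 for the trivial partition at γ = 1.
Louvain's gain tolerance (1e-12), the oracle tie-breaks, and the snapping of
sub-1e-12 cosine values are the only numerical thresholds in the package.

## Known limitations

* Louvain is a greedy heuristic: on ~8% of small random weighted graphs it
  returns a partition strictly below the enumerated optimum (it never exceeds
  it).  Alternative algorithms (Leiden, Infomap, Barber's bipartite
  modularity) are out of scope.
* The γ convention multiplies the null term (Reichardt–Bornholdt).  Other
  tools may scale modularity differently, so absolute Q values are comparable
  only within a convention.
* The packaged term→superclass map is synthetic; analyses of real data must
  supply their own mapping table.
* Greedy best-match concordance can differ from an optimal assignment when
  Jaccard ties interleave; the full matrix is always emitted for audit.
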