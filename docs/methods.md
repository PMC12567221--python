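# Methods

This note documents the models and procedures `herbnet` implements, the
design of the synthetic-data generators, the numerical choices, and the
limitations the test suite exposes.  Nothing here states an empirical result
the tests or `scripts/acceptance.py` do not themselves compute.

## 1. Target-screening funnel

Compounds carry two ADME axes: oral bioavailability (OB, percent of an oral
dose reaching systemic circulation, 0–100) and drug-likeness (DL, similarity
to known drugs, 0–1).  `filter_adme` keeps records with OB ≥ 30 and
DL ≥ 0.18; every threshold comparison in the package is inclusive (≥), and
thresholds are configurable.

Gene symbols are normalised by trimming and uppercasing.  Full identifier
remapping through a live service is out of scope; `union_targets` accepts a
user-supplied alias table instead.  Disease targets carry a nonnegative
relevance score; `screen_disease_targets` de-duplicates symbols first (each
symbol keeps its maximum score), then retains scores at or above the median.
The median of an even count is the mean of the two central order statistics,
here and in the network screening.  Common targets are the plain symbol
intersection of the drug-target union and the screened disease targets.

## 2. Six-metric PPI hub screening

Edges carry a confidence score in [0, 1]; `filter_edges` keeps scores
≥ `min_score` (default 0.700, the conventional STRING high-confidence cut)
and drops nodes left without edges.  Scores play no further role: the
centralities are purely topological.

Per node of the current subnetwork (N nodes):

* **DC** — degree.
* **BC** — betweenness as unnormalised pair counts,
  Σ_{s≠v≠t} σ_st(v)/σ_st, each unordered pair counted once.
* **CC** — Wasserman–Faust component-scaled closeness:
  ((n_c−1)/Σ_{u∈C(v)} d(v,u)) · ((n_c−1)/(N−1)) with C(v) the connected
  component of v, size n_c.  On a connected graph this equals the plain
  within-component closeness (n_c−1)/Σd.  The scaling matters on fragmented
  graphs: plain within-component closeness assigns every 2-node component
  the value 1.0, so after a confidence filter shatters a sparse background,
  dyads outrank genuine hub modules at the median and the screen keeps the
  wrong nodes.  The component-scaled form penalises small components
  instead; this is also the networkx default.
* **EC** — nonnegative principal eigenvector of the adjacency matrix, unit
  2-norm.  On a disconnected graph the Perron vector is supported on the
  component with the largest adjacency spectral radius; when several
  components tie numerically the one containing the smallest node label is
  used, keeping results order-independent and deterministic.
* **NC** — Σ over incident edges of the edge clustering coefficient
  ECC(u,v) = t(u,v)/min(d_u−1, d_v−1), where t(u,v) counts triangles on the
  edge; ECC is defined as 0 when the denominator is 0.
* **LAC** — mean degree of v's neighbours inside the subgraph induced by
  those neighbours (0 for isolated nodes).

`median_screen` (default 2 rounds) keeps nodes whose six values are all at
or above the per-metric medians of the current round, then induces the
subnetwork on the survivors and repeats.  Comparisons use a tolerance of
1e−9·(1+|median|) so analytically tied values (eigenvector entries of
symmetric nodes differ only by floating-point noise) are not split.  A round
that eliminates every node is recorded in the trace with a warning rather
than raising, and the empty network is returned.

**Hand-checkable example.**  K4 with a pendant attached to vertex 1: DC
medians 3, BC 0, CC 0.8, NC 3, LAC 2.  Vertex 1 fails the LAC median (its
pendant dilutes the neighbourhood), the pendant fails DC/CC/EC, and the
survivors are the triangle {2,3,4} — a vertex-transitive fixed point for
every later round.

**Limitation: conjunction screening vs dense modules.**  Betweenness
structurally disfavours the interior of a dense module: shortest paths split
over the module's redundant members, while cut vertices of a sparse
background accumulate whole path counts.  Consequently a planted clique in a
random background does *not* reliably pass two full six-metric rounds: some
members sit below the BC median, and a background pendant that survives the
confidence filter both fails the screen itself and drags its attachment
point below the LAC median (the K4-pendant mechanism).  Across the
regimes we scanned, two-round screening recovers the bulk of a planted
module with essentially no false hubs, but exact recovery of every member is
a coin flip.  The property tests therefore assert no-false-hub behaviour and
majority recovery, not exact set equality; analysts should read hub lists
the same way.

The compound–target network is the bipartite restriction of the
compound→target mapping to ADME-passing compounds and surviving hubs;
compounds with no retained edge are dropped and the rest are ranked by
degree, ties broken lexicographically by id.

## 3. Over-representation analysis

For a query of n genes in a universe of N, a term with K genes and overlap
k ≥ 1 gets the exact hypergeometric upper tail P(X ≥ k) (via
`scipy.stats.hypergeom`; the test suite checks it against exact rational
enumeration).  Benjamini–Hochberg adjustment is applied within each category
(BP/CC/MF/pathway) because per-category term lists are the reporting unit;
a flag switches to global adjustment.  Terms with k = 0 are omitted rather
than reported at p = 1.  The universe defaults to the union of all
annotation genes — the most conservative self-contained choice — and can be
overridden; query symbols outside the universe are dropped with a logged
warning.  `top_terms` removes terms whose names match user-supplied
exclusion regexes (the customary pruning of context-irrelevant disease
pathways), then returns up to 10 terms per category by ascending p, ties
broken by term id.  Absolute term counts from live GO/KEGG releases are
database-version-dependent and are not a target of this package.

## 4. Metabolomics pipeline

**Preprocessing.**  Intensities are nonnegative; zeros are replaced
column-wise by half the smallest positive value, then (by default) log
transformed, always column-centered, and unit-variance scaled (ddof = 1).
Pareto scaling and no scaling are available.  All-zero columns, and
zero-variance columns under unit-variance scaling, are dropped and named in
the returned metadata.  All downstream statistics (t-tests, directions)
operate on this processed scale; log-normal intensities become Gaussian
under it, matching the t-test's assumptions.

**PCA** is a thin wrapper over scikit-learn (full SVD), returning scores,
orthonormal loadings and explained-variance fractions.

**OPLS-DA.**  Group labels are coded y ∈ {−1, +1} (lexicographically first
level → −1).  Orthogonal signal correction runs `n_ortho` times (default 1;
component counts are rarely reported in applied studies and one orthogonal
component is the common choice): w ∝ X'y normalised, t = Xw, p = X't/t't,
w⊥ = p − (w'p/w'w)·w normalised, t⊥ = Xw⊥, deflate X by t⊥p⊥'.  The loop
stops early if no orthogonal variation remains.  One predictive PLS
component is then fitted on the filtered matrix.  R²Y = 1 − SS_res/SS_tot on
the training labels.  Q² = 1 − PRESS/SS_tot under stratified k-fold
cross-validation (default 7 folds, reduced with a warning when a group is
smaller) with centering, the orthogonal filter and the predictive component
all refit per fold; fold assignment derives from the seed.  With
`n_ortho=0` the model is exactly single-component PLS1-DA (verified against
scikit-learn's PLSRegression).  VIP is computed on the predictive component,
VIP_j = √p·|w_j|, the convention for biomarker ranking, giving the identity
mean(VIP²) = 1; a generalised multi-component formula weighted by explained
class variance is available.  A permutation test on the results object refits
the full pipeline under label permutation and returns the Q² null sample.
Reported class-variance statistics are R²Y (not R²X).

**Differential screening.**  For a two-group comparison: VIP from the
OPLS-DA fit of the processed submatrix; per-metabolite two-sided Welch
t-test (Student optional) on the processed scale; direction = sign of the
processed-scale mean difference.  A metabolite is significant iff VIP > 1
*and* p < 0.05, both strictly.  Metabolites dropped in preprocessing are
reported with VIP 0, p 1, direction 0 so every result list covers the full
metabolite universe.

**Three-group comparison.**  One-way ANOVA per metabolite plus Dunn's
rank-based post test: pooled-sample ranks, tie-corrected variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)), pairwise z statistics, two-sided normal
p-values, BH-adjusted within each metabolite's three pairs (the post-test
correction unit).  No installed package provides Dunn's test, so it is
implemented here and checked against a hand-worked example.  A metabolite
constant across all samples is reported with p = 1 and a degenerate flag.

**Reversal biomarkers.**  Metabolites significant in both model-vs-control
and treatment-vs-model with opposite directions, ordered by id.  A reversal
is the signature of a treatment pushing a disease-altered metabolite back
toward normal.

**Limitation: spurious reversals.**  The two comparisons share the model
group.  A chance excursion of a null metabolite's model-group mean makes it
significant in *both* comparisons with automatically opposite directions —
regression to the mean wearing a reversal costume.  At the default study
conditions (10 samples/group, 100 metabolites, ~90 null) this produces on
the order of one spurious reversal per run, at any sample size, because it
is driven by the false-positive rate, not power.  The acceptance suite
measures this honestly: planted reversals are always recovered, but the
detected set equals the planted set only in a minority of seeds.  Real
studies using this screening rule face the same risk; treating reversal
lists as candidates for targeted validation, or adjusting the pairwise
p-values, is advisable.

## 5. Synthetic-data generators

All generators are pure functions of their arguments including the seed; a
scenario seed fans out to per-generator child seeds by the fixed offsets in
`herbnet.simulate.SEED_OFFSETS`.

* **Compound library** (default 210 compounds, 30 active — the shape of a
  typical untargeted compound identification run): active compounds draw
  OB ~ U[30, 100], DL ~ U[0.18, 1]; inactive compounds fail on a randomly
  chosen axis (OB, DL, or both) drawn uniformly below the threshold, so
  boundary behaviour is exercised.
* **PPI network**: Erdős–Rényi or Barabási–Albert background with a planted
  clique on the first `planted_clique` labels; background edge scores
  U[0, 1], clique edges U[0.9, 1] so the module survives the 0.700 filter
  intact.  The default scenario uses 60 common targets, background density
  0.03 (matching the edge density of typical high-confidence PPI exports)
  and an 8-node module.
* **Annotations**: random term–gene sets with categories cycling through
  BP/CC/MF/pathway; term `T0000` equals the planted gene set (the hub
  module in the default scenario).
* **Metabolomics** (default 10 samples/group, 100 metabolites, 10
  differential per comparison, 4 reversed, effect 3 sd): log-intensities
  are baseline_m + shift + noise with per-metabolite baselines N(0, 1) and
  noise N(0, noise_sd); intensities are their exponential (log-normal, so
  the default log transform recovers Gaussianity).  Model-vs-control
  metabolites shift the model *and* treatment groups by
  ±effect·noise_sd (the treatment starts at the disease level);
  treatment-vs-model metabolites shift the treatment group from there;
  reversed metabolites carry both shifts with opposite signs, returning the
  treatment group to the control level.  The two planted sets overlap
  exactly in the reversed metabolites.  Group sizes are configurable; 10
  per group is a realistic serum-metabolomics cohort and gives essentially
  full power at 3 sd.
* **Disease-target table**: the planted common set receives the top
  exponential relevance scores, the remaining disease genes are disjoint
  from the drug targets, so the median screen provably retains the planted
  set and the intersection equals it exactly.
* **Biomarker link tables**: 24 proteins and 18 pathways distributed over
  the reversed metabolites with one designated high-degree core biomarker.

What the generators do *not* emulate: mass spectra, retention times,
adducts, missing-value structure, batch effects, inter-metabolite
correlation, or database-scale annotation redundancy.  Passing tests
demonstrate correct recovery of planted structure under idealised noise,
not robustness to those real-data artefacts.

## 6. Pipeline, determinism and problem sizes

`run_pipeline` executes ADME filtering → target union/median
screen/intersection → PPI confidence filter → two-round hub screen →
compound–target network → ORA → the two OPLS-DA differential screens →
three-group ANOVA/Dunn → reversal detection → biomarker–target–pathway
network, writing every intermediate artifact and a JSON report whose counts
are all re-derivable from the artifacts (audited by a test).  All randomness
flows from the config seed; two runs of the same config are byte-identical.
A stage failure still writes the report with the failed stage named and
preserves earlier artifacts.

Default problem sizes (60-node networks, 100-metabolite matrices, 20-seed
replications, 200-graph oracle sweeps) keep the full test suite and the
acceptance script in the tens of seconds on one CPU while leaving every
statistical property measurable; all sizes scale up through the config.
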