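# herbnet

Network-pharmacology and untargeted-metabolomics screening for herbal-formula
mechanism studies, as one tested pipeline.

Studies of multi-herb preparations typically chain the same computational
funnel: candidate compounds are filtered on ADME properties (oral
bioavailability OB ≥ 30 %, drug-likeness DL ≥ 0.18); their putative protein
targets, pooled from several databases, are intersected with disease-gene
tables screened at the median relevance score; the common targets' STRING-style
protein–protein interaction network (confidence ≥ 0.700) is reduced to hub
targets by iterative median screening on six topological centralities; the
hubs are interpreted through hypergeometric over-representation analysis; and
in parallel, serum metabolomics is screened for differential metabolites by
OPLS-DA (VIP > 1 and t-test p < 0.05), three-group ANOVA with Dunn's
BH-corrected post test, and *reversal biomarkers* — metabolites the disease
model shifts one way and the treatment shifts significantly back.  Those
biomarkers, their associated proteins and pathways form a tripartite network
whose highest-degree nodes are the core biomarkers.

In practice each arrow in that chain lives in a different tool (Cytoscape
plug-ins, web services, R scripts).  `herbnet` implements the whole chain as
a library plus CLI, and ships a synthetic-data module that generates every
input with *planted ground truth* — known active compounds, a planted hub
module, a planted enriched term, planted differential and reversed
metabolites — so every stage, and the pipeline end to end, is testable
without any database export.

## The statistics at the core

**Six-metric hub screening.** For the current subnetwork each node gets
degree (DC), unnormalised betweenness (BC), component-scaled closeness (CC),
eigenvector centrality (EC, the nonnegative principal eigenvector of the
adjacency matrix), edge-clustering-based centrality
NC(v) = Σ_{u∈N(v)} ECC(v,u) with ECC(u,v) = triangles(u,v)/min(d_u−1, d_v−1),
and local average connectivity LAC(v) = mean degree of N(v) inside the
subgraph induced by N(v).  A node survives a round iff all six values are at
or above that round's per-metric medians; survivors induce the next round's
subnetwork (default two rounds).

**OPLS-DA.** Groups are coded y ∈ {−1, +1}; `n_ortho` components of
class-orthogonal variation are removed (orthogonal signal correction:
w ∝ X'y, t = Xw, p = X't/t't, w⊥ = p − (w'p/w'w)w, deflate X by t⊥p⊥'),
then one predictive PLS component is fitted.  R²Y is the explained class
variance in fit; Q² = 1 − PRESS/SS under stratified k-fold cross-validation
with the full pipeline refit per fold; VIP_j = √p·|w_j| on the predictive
component, so mean(VIP²) ≡ 1.  `OPLSDA(...).fit()` returns a results object
with `summary()`, and `results.permutation_test()` gives the permutation
null of Q².

**Enrichment.** Exact hypergeometric upper tails P(X ≥ k) with
Benjamini–Hochberg adjustment per category (BP/CC/MF/pathway), top-k
selection with exclusion patterns.

## Worked example

```python
from herbnet import filter_edges, median_screen, screen_differential, find_reversed
from herbnet.simulate import gen_metabolomics, gen_ppi

# hub screening of a PPI network with a planted 8-node module
ppi, module = gen_ppi(n_nodes=40, model="erdos_renyi", density_param=0.05,
                      planted_clique=8, seed=2)
hubs, trace = median_screen(filter_edges(ppi, 0.700), rounds=2)
print([(r.nodes_before, r.nodes_after) for r in trace.rounds])
print(sorted(hubs.nodes()), set(hubs.nodes()) <= set(module))

# differential and reversed metabolites on a planted three-group matrix
im, truth = gen_metabolomics(n_per_group=10, n_metabolites=100, seed=0)
mc = screen_differential(im, "control", "model", seed=0)
mt = screen_differential(im, "model", "treatment", seed=0)
reversed_markers = find_reversed(mc, mt)
print([m.metabolite_id for m in reversed_markers])
print(sorted(truth.reversed_metabolites))
```

prints

```
[(21, 11), (11, 6)]
['G0002', 'G0004', 'G0005', 'G0006', 'G0007', 'G0008'] True
['M0004', 'M0028', 'M0045', 'M0055']
['M0004', 'M0028', 'M0045', 'M0055']
```

— the confidence filter and two screening rounds localise onto the planted
module: all six surviving hubs are module members, none are background
(module members that picked up chance background attachments can be pruned
by the screen; see the limitations section of `docs/methods.md`).  The
reversal screen returns exactly the four planted reversed metabolites, each
significant in both comparisons with opposite directions of change.

The same run from the shell:

```
herbnet run --out results/run1 --seed 0
herbnet hub-screen --min-score 0.700 --rounds 2 --in edges.tsv --out hubs.sif
herbnet metabolomics --in intensities.tsv --compare control model \
    --compare model treatment --out results/mets --seed 0
```

`run` writes every intermediate artifact plus `report.json` with all stage
counts; two runs with the same config are byte-identical.

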