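# Methods

`semiconn` implements a semi-metric analysis of multi-metric weighted
structural brain networks (SBNs): per-subject networks are normalised,
topologically filtered, fused into one integrated network, profiled for
indirect-path (semi-metric) behaviour at six spatial scales, and compared
between two groups with nonparametric tests under per-family FDR control.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Data model

A connectome is a symmetric nonnegative `N x N` matrix with zero diagonal
over a region table that assigns every node a name and a hemisphere
(default: the 90-region AAL cerebrum, 45 per hemisphere; hemisphere
membership always comes from the table, never from index parity).  Each
subject carries nine layers — FA, MD, RD, NS, PS, SLD, TV, TL, ED — one
connectivity metric each.  Matrices are plain delimited text; node indices
are 1-based externally.

Normalisation divides every layer by its maximum edge weight (max = 1).
Distance-like metrics (MD, RD, TL, ED) are consumed as-is after
normalisation; no inversion is applied.  This is the literal reading of the
construction being reproduced, and it is a known caveat: for those layers
"large weight" means *dissimilar* rather than *strongly connected*, and the
fusion stage treats all layers alike.  The integration only consumes the
layers' mutual dissimilarity structure, so the caveat affects
interpretation of single layers, not the mechanics.

Network descriptors: sparsity = existing edges / `N(N-1)/2` (4005 at
N = 90); strengths are sums of edge weights with **each undirected edge
counted once**, so left + right + interhemispheric = global exactly.  The
convention is stated because published descriptor tables in this literature
do not always reconcile under a single counting convention; this package's
outputs are self-consistent by construction.

## OMST topological filtering

Edge-disjoint minimum spanning trees (distance `1/w`) are extracted
iteratively; after round `k` the retained graph (union of the first `k`
trees) is scored by `global efficiency − cost`, where cost is the retained
fraction of total edge weight (denominator fixed per subject) and global
efficiency is the mean inverse shortest-path distance over ordered pairs
(`1/w` distances, disconnected pairs contribute 0).  The round maximising
the objective wins; its union is the filtered network.  Guarantees:
connected output, round-1 MST always retained, retained weights unchanged.

Numerical choices:

* MST distance is `1/w` rather than `1/w − 1`; MSTs are invariant to
  strictly monotone transforms of the distances, so the trees are
  identical either way, and `1/w` is the standard efficiency convention.
* Ties break deterministically by (distance, smaller endpoint, larger
  endpoint), making output platform-independent.
* The scan stops early once the objective has declined for 3 consecutive
  rounds (`patience`; `patience=None` scans every feasible round, at most
  `floor(M/(N−1))`).  Observed objective curves rise to a single early
  peak and then decline monotonically — the efficiency term saturates
  while cost grows steadily — so the patience rule returns the global
  maximum in practice while cutting the scan roughly in half.  The
  brute-force equivalence tests run with `patience=None`.

## Layer fusion by graph diffusion distance

The graph diffusion distance (GDD) between two layers is
`max_t || exp(−t L_a) − exp(−t L_b) ||_F` with `L = D − W` the weighted
Laplacian.  Kernels are evaluated exactly via the Laplacian
eigendecomposition; the Frobenius norm uses
`||A−B||² = tr A² + tr B² − 2 tr AB`, with `tr AB` computed from the
eigenbases (`M = V_aᵀV_b`), so no matrix exponential is ever formed.  The
diffusion-time search scans 100 log-spaced points in `[10^-2.5, 10^2.5]`
and applies one golden-section refinement around an interior grid maximum
(relative `xtol` 1e-4); boundary maxima are taken as-is.

Layer weights: the default rule gives each layer a weight proportional to
its **mean GDD to the other layers** (complementary layers score high,
redundant layers low), normalised to sum to 1.  The verbal description
this implements ("more informative gets a higher weight") admits other
readings, so `min` (minimal off-diagonal GDD) and `softmax` (exponentiated
standardised mean) strategies are selectable for sensitivity analysis.  If
all pairwise distances vanish the rule degenerates and uniform weights are
returned with a warning.  The integrated network is the weighted sum of
the *filtered* layers (no re-filtering), re-normalised to max 1.

## Semi-metric analysis

Distance transform `d_ij = 1/w_ij − 1` on existing edges (`+inf` absent,
0 diagonal; defined for normalised weights in (0, 1]).  All-pairs shortest
paths `dt` via Johnson's algorithm (exact; zero-length edges from
weight-1 edges are preserved).  Per-edge semi-metric ratio
`SMR_ij = d_ij / dt_ij ≥ 1`; an edge is *semi-metric* iff
`SMR > 1 + 1e-9` (float shortest paths can differ from the direct distance
at machine precision on metric edges), *metric* otherwise.  SMR is defined
only on existing edges; absent pairs enter no numerator or denominator.

Scales (all derived from the one full-graph SMR matrix; hemispheric values
classify edges by endpoint location rather than recomputing paths on
subgraphs):

* SMR fractions: global, intra-left, intra-right, interhemispheric —
  semi-metric edges / existing edges of each scope;
* BAI = left / right SMR fraction (> 1 leftward; an error is raised when
  the right fraction is 0, rather than returning an infinite index);
* SMP: per node, semi-metric incident edges / degree; the global value is
  the mean over all nodes and hemispheric values the means over each
  hemisphere's nodes (the node-normalised reading of the network-level
  percentage formula, which the surrounding construction assigns to the
  node scale).

A worked five-node example ships as `make_toy_network()`.  Its published
caption compares raw proximity-weight sums along detours (0.3 and 0.6
against a direct 0.4) and on that arithmetic calls edge 2–3 semi-metric;
under the distance transform + shortest-path definitions implemented here
every edge of that toy graph is metric.  The package reproduces the
caption's path-weight arithmetic exactly (`path_weight_sum`) and follows
the formal definitions for classification; the discrepancy is inherent to
the source material and documented rather than resolved.

## Group statistics

Two-sided Wilcoxon rank-sum per comparison (exact null when
`min(n, m) ≤ 10` without ties, tie-corrected normal approximation with
continuity correction otherwise; all-identical samples return p = 1 by
convention).  Benjamini–Hochberg step-up within each declared family:
per-edge SMR (≤ 4005 tests), SMR scales (5), SMP scales (3), per-node SMP
(N); the descriptor family (sparsity + 4 strengths) and the volumetric
asymmetry family (3 networks) are screened uncorrected at p < α, mirroring
how they are treated as secondary checks in this literature.  Direction is
the sign of the rank-biserial correlation.

Per-edge missing data: a subject contributes to an edge's test only if the
edge exists in their integrated network, and edges present in fewer than
50% of either group's subjects are excluded (count logged).  Filtered
networks are sparse, so most possible edges never reach testing; the
threshold is this package's policy, exposed as configuration.

## Volumetric asymmetry

`BAI_vol` = left/right ratio of ICV-normalised volume sums over a
bilateral subnetwork.  Shipped subnetworks: the 13-region language set,
a subcortical set, and the whole cerebrum.  The subcortical membership
(hippocampus, amygdala, caudate, putamen, pallidum, thalamus) is the
conventional AAL subcortical grouping, chosen because the construction
reproduced names "a subcortical network" without enumerating it; this is
an interpretation.  On non-AAL synthetic region tables the named sets
cannot resolve and size-matched stand-ins (first 13 / next 6 base regions,
labelled `*_synthetic`) are substituted.

## Synthetic cohorts

The cohort data this pipeline was designed around is access-restricted, so
all empirical checks run on synthetic cohorts from `semiconn.synthetic`.
What the generator emulates:

* geometry: half the nodes placed uniformly in a unit cube, the other half
  mirrored; intra-hemispheric edge strength `exp(−distance / 1.0)`, the
  strongest 60% of intra-hemispheric pairs kept (`baseline_density`), the
  right block an exact mirror of the left; interhemispheric block at half
  that density with all homotopic pairs present; a maximum-weight spanning
  tree (hemisphere-symmetrised) unioned in so every subject is connected;
* layers: rank-preserving noisy transforms of the shared backbone —
  per-layer power exponents in [0.7, 1.4] plus log-normal noise of scale
  `noise_sd = 0.15` whose correlation across layers is
  `layer_correlation = 0.9`.  The layers are *not* biophysically distinct
  FA/MD/…; the fusion stage only consumes their dissimilarity structure;
* group effect: in the high group, `effect_edge_fraction = 0.25` of the
  intra-left edges (sampled among above-median-weight edges, i.e. the
  connections the filter actually retains) are multiplied by
  `effect_attenuation = 0.3`, each in a random 70% of the layers.
  Weakening an edge in most-but-not-all layers makes the per-layer filter
  drop it where attenuated while the remaining layers keep it present, so
  the fused network carries the direct route at reduced weight and
  shortest paths reroute around it — left-hemisphere semi-metricity rises.
  Attenuating an edge in *every* layer instead simply deletes it from all
  filtered layers, which removes semi-metric-prone edges and lowers the
  left fraction — the opposite of the intended mechanism; the per-layer
  sampling is therefore a structural requirement, not a tuning knob.
  `effect_attenuation = 1` is the exchangeable null (the high branch draws
  nothing extra from the generator, so the groups share one law);
* seeding: per-subject seeds derive from `(seed, group, index)` via
  `numpy.random.SeedSequence`; identical configs give byte-identical
  cohorts;
* volumes: fixed mirrored base volumes per region, left side scaled by
  `1 + asymmetry_shift`, log-normal subject noise tied to `noise_sd`
  (exact ratio recovery at zero noise), equal-mean hemispheric ICVs.

Calibration of the generator's free constants (decay scale, density, noise
scale, layer correlation, the 70% layer fraction and the above-median edge
eligibility) was done once against the structural regime the pipeline is
meant to operate in — an OMST objective that peaks past round one,
integrated sparsity of order 0.1 (observed ≈ 0.07–0.09), a baseline
semi-metric fraction near 0.5, and an injected effect that expresses
through the full pipeline — and then frozen.

What passing the synthetic suites does **not** show: that the pipeline
recovers effects in real diffusion-MRI cohorts (real metric layers are
biophysically heterogeneous, not rank-preserving copies), that the
descriptor family stays null under a real group difference (the synthetic
lesion visibly reduces left-hemisphere strength, which real cohorts need
not do), or anything about tractography, registration or parcellation
upstream of the matrices.

## Replicate suites and problem sizes

* Null calibration: 25 replicate cohorts, 45 subjects per group,
  40-node networks, `effect_attenuation = 1`.  Per family, the pooled
  post-FDR rejection rate must not exceed α + 2·SE(binomial).  The reduced
  node count is a deliberate scale-down: type-I validity of a rank test
  under exchangeable groups does not depend on network size, and the small
  networks keep the suite inside a few CPU-minutes.
* Effect recovery: 25 replicate cohorts (20 in the faster standalone
  reproduction script) at the full 90-node scale, 45 per group,
  attenuation 0.3 on 25% of intra-left edges.  Pass rule:
  `smr_left` and BAI FDR-significant with direction high > low in ≥ 80% of
  replicates; `smr_right` and `smr_inter` non-significant in ≥ 80%.
  Measured over 16 independent development seeds: 15/16, 15/16, 16/16,
  15/16 respectively (~94%), so the ≥ 80% rule has comfortable margin.

## Known limitations

* The fusion weight rule is one admissible reading of a verbal
  description; alternatives ship as strategies but only `mean` is tested
  against the replicate suites.
* Distance-like layers are not inverted before fusion (see above).
* BAI is undefined (raised as an error) when the right hemisphere has no
  semi-metric edges; realistic densities never hit this, but pathological
  inputs will.
* The per-edge ≥ 50% presence rule and the uncorrected screening of the
  descriptor/volumetric families are policies, not mathematics; both are
  configuration-visible.
* GDD is a pseudo-metric: co-spectral layer pairs (measure zero for noisy
  data) would receive zero distance.
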