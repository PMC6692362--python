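# Methods

This note records the models, conventions and numerical choices behind
`vasculotopo`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic phantoms do and do not emulate.

## Coordinate and data conventions

Volumes are boolean arrays indexed (z, y, x) with physical voxel spacing in
the same axis order; the default grid is the light-sheet acquisition pitch
of 5 µm between planes and 3.25 µm in-plane. All physical quantities are
micrometres internally; densities are reported per mm³ after conversion.
Graphs are `networkx` multigraphs: parallel edges are distinct vessel loops
and self-loops are legitimate closed vessels, so neither is ever collapsed
except where a metric's definition demands a simple graph (clustering,
path lengths). Degrees count self-loops twice, preserving Σk = 2·N_e.

## Volume conditioning

* **Smoothing** uses an isotropic σ in voxel units despite anisotropic
  physical spacing — deliberately, because that is how binary stacks are
  conditioned in the imaging pipeline this package mirrors; a physically
  isotropic alternative is a one-line change (pass per-axis sigmas to the
  Gaussian) but is not the default. The re-binarization threshold is half
  the *global* maximum of the smoothed field; with bulk foreground present
  the maximum saturates at ~1 and the cut is effectively 0.5. A local-max
  reading of the rule would behave differently only in pathological volumes
  with no bulk foreground.
* **Hole filling** labels the background with 6-connectivity (the standard
  dual of 26-connected foreground) and fills components that do not reach
  the volume border.
* **Speck removal** deletes components whose physical volume is below that
  of a 6 µm-radius sphere (904.78 µm³ = 17.1 voxels at the default grid, so
  the cut separates 17- from 18-voxel bunches).
* **Circumferential thinning** defines the boundary layer as foreground
  voxels with at least one 6-connected background neighbour and removes it,
  always retaining skeleton voxels; it exists to counter fluorescent
  over-segmentation that inflates vessel calibre.
* In the bundled pipeline, smoothing is applied to file-based and
  noise-corrupted input but skipped for clean synthetic volumes: phantom
  tubes are rendered at their exact width, so a σ = 1 kernel would erode
  capillaries thinner than itself and fragment topology, whereas real
  segmentations arrive over-thick and survive it. This is an input-regime
  decision, not a change to the operation itself.

## Skeleton to graph

Thinning is Lee-style 3D medial-axis thinning (scikit-image), which
preserves digital topology; we promise topological agreement with the
classic ImageJ implementation on the phantom suite, not voxel-exact output.
Tagging follows the neighbour-count rule (endpoint < 2, slab = 2,
junction > 2 skeleton voxels among the 26-neighbours). Junction voxels are
merged into branch nodes by strict 26-adjacency transitive closure, with
the node placed at the cluster's voxel centroid; this merging — not any
distance parameter — is what produces the high-degree vertices (k ≥ 20)
where consecutive bifurcations sit closer than the smallest vessel
diameter. Degree-2 nodes arising from tagging are retained; no stub
pruning is performed (a prune length would be an arbitrary manipulation of
the data). Slab cycles that touch no node voxel anywhere are anchored at
their lexicographically smallest voxel as a degree-2 self-loop node, which
keeps the handshake identity and the loop itself.

Under the tagging rule, boundary-perturbation stubs appear as k = 1 tips
attached to k ≥ 3 junctions rather than as k = 2 nodes; descriptions of
such stubs as degree-2 artifacts refer to the merged view after cluster
merging absorbs the stub's base.

## Vessel geometry

Segment length is the sum of physical step lengths along the centerline
voxel path; the endpoint separation d is the Euclidean distance between
the first and last voxels of that path. Using the path's own terminal
voxels (rather than merged-cluster centroids) keeps the invariant
τ = l/d ≥ 1 exact, at the cost of a slightly different d for high-degree
nodes whose cluster centroid sits off the contact voxel. Self-loops have
d = 0; their τ is undefined and excluded (with a logged count) from
tortuosity statistics.

Radii sample the anisotropic Euclidean distance transform at interior
(slab) centerline voxels only — junction voxels conflate adjoining
vessels. Surface area is the local-cylinder lateral sum Σ 2π r_i Δl_i;
voxel-face counting was rejected because face areas overestimate
anisotropically at this voxel size. On a straight digital cylinder the
26-connected path inflates l by at most ~8%, which bounds the tolerance
used in the τ oracles (a quarter-circle arc converges to
(π/2)/√2 ≈ 1.1107 from above within that bound).

Tiling statistics use half-open 500 µm boxes; a segment belongs to the box
containing its centerline's median voxel (one box per segment, no double
counting), and boxes with mask coverage below 50% are excluded while
partial boxes use their actual in-mask volume. Summary tables report
arithmetic means with *average directed deviations* — the mean deviation of
values above the mean and below it, reported separately — for the
log-normally distributed quantities (r̄, l, A), and median plus 95%
empirical quantile (linear interpolation between order statistics) for the
exponentially distributed tortuosity. Multiplicative log-SD bounds would
be a defensible alternative for the directed deviations; the additive
convention was chosen and is fixed.

Shrinkage correction: an isotropic volume loss of fraction s (default 0.40
from optical clearing) rescales lengths and radii by (1−s)^{−1/3}, areas by
(1−s)^{−2/3} and volumes by (1−s)^{−1}; densities divide accordingly. The
correction is exactly invertible with s' = −s/(1−s).

## Topology metrics

The degree-exponent fit is ordinary least squares of log10 P(k) on log10 k
over observed degrees k ≥ 5 — the straight-line-on-log-axes convention —
not a maximum-likelihood estimator. An optional `min_count` drops degree
bins observed fewer than that many times: singleton tail bins carry ~100%
relative noise and systematically flatten steep tails (for a generative
exponent of 8.7 at n = 5·10⁴ the plain fit reads ~0.6 too shallow; with
`min_count=2` recovery is within a few percent). Recovery experiments use
`min_count=2`; empirical vascular fits use the plain convention.

Clustering is computed on the simple-graph reduction via sparse matrix
triangle counting (fast enough for 10⁵–10⁶ nodes); nodes with k < 2
contribute C_i = 0 and are included in the mean, the convention under
which the Erdős–Rényi mean converges to the edge probability p (an
exclusion variant is available). The hierarchical exponent β is a robust
(Tukey-bisquare IRLS) fit of log C_i on log k_i over nodes with C_i > 0 and
k ≥ 3. Two diagnostics guard it: `support_fraction`, the share of eligible
nodes carrying any triangle — in sparse random graphs the few
triangle-bearing nodes trace C = 2/(k(k−1)) exactly, a pure selection
artifact, so fits with support below 5% are flagged invalid — and an
`aggregate_by_degree` mode that fits per-degree mean C(k), the appropriate
estimator for deterministic constructions where node multiplicity would
mass-weight the regression (the deterministic hierarchical model yields
β ≈ 1.11 aggregated, versus ~0.6 under node-mass weighting).

Path statistics average unweighted geodesics over connected pairs only.
Exact all-pairs BFS is used up to 2,000 nodes; above that, 1,000 uniformly
sampled BFS sources give an unbiased estimate of L (within ~2% on 10⁴-node
test graphs) and a lower bound on D, flagged as approximate.

## Community analysis

Modularity is evaluated exactly from its defining double sum, with the
self-loop convention A_ii = 2w so that weighted degrees and the edge-weight
normalisation stay consistent. Louvain unfolding delegates the greedy
optimisation to networkx's implementation; every intermediate level is
retained with its Q (each level is a local maximum at a different scale),
and Q is non-decreasing across levels. Node-sweep order is randomised, so
the partition is made a pure function of (graph, seed, restarts) by running
`restarts` independent sweeps (default 5) and keeping the best final Q.
Basic vessel graphs are clustered with unit edge weights; the recursion on
meta-levels uses merged edge multiplicities as weights.

Isolated communities (perimeter P = 0) with fewer than 20 internal edges
are dropped from downstream statistics — they are disconnected boundary
clippings, not supply units. Meta-edge weights count crossing vessel
segments, so the weight sum equals N_ice = ΣP_j/2 identically. C_c, L_c and
D_c are computed on the simple unweighted meta-graph: hop counts, not
weighted lengths, which is the scale on which mean community separations
of ~2–5 hops are meaningful. Community-degree histograms use 10
logarithmic bins per decade with geometric bin centers. The neighbour-
degree average ⟨k_c1⟩ is unweighted over unique meta-neighbours (a
weight-proportional variant exists behind a flag). ξ, κ and β all use the
same bisquare IRLS log–log fit. The resolution parameter is fixed at 1; no
multi-resolution sweep is attempted.

One reference value is knowingly not reproduced: near-zero maximum
modularity (~10⁻⁷) for Louvain-clustered sparse Erdős–Rényi graphs.
Standard Louvain finds substantially positive Q (~0.5–0.7) on sparse
random graphs — a well-documented property of modularity optimisation, not
an implementation defect — and no reading of the algorithm we can construct
yields 10⁻⁷. The package reports what it computes.

## Cohort statistics

Kruskal–Wallis (tie-corrected, chi-square approximation) via scipy is the
only test offered, applied to per-specimen summary values — the specimen is
the unit of analysis; pooled per-vessel testing is deliberately not
provided, to avoid pseudoreplication over 10⁵–10⁶ segments. No
multiple-testing correction is applied, and the reported p-values should be
read accordingly. With a single specimen per group the test is undefined
and reported as such.

## Synthetic phantoms: what they emulate, and what not

The generator produces spatial tube networks with known ground truth on
the anisotropic acquisition grid. Healthy-like tissue is modelled as
boundary-rooted bifurcating trees (radius tapering ×2^{−1/3} per
generation, branch angles ~38°) whose leaves are progressively closed into
a capillary mesh until the calibrated length density (980 mm/mm³) is
reached, with the endpoint (k = 1) node fraction calibrated to 0.11.
Tumor-like tissue starts sparser (730 mm/mm³, shorter sprouts, tighter
closure radius), deletes a random 8% of segments, inserts blind sprouts,
adds three-edge loop closures (12% of nodes) to emulate angiogenic vessel
loops, doubles the sinusoidal tortuosity amplitude, and calibrates
endpoints to 0.20. These mechanisms are the minimal set that reproduces
the qualitative contrasts of interest — endpoint enrichment, higher local
clustering, lower length density, smaller and more fragmented communities
— and the two presets differ in those directions on 6-vs-6 cohorts.

Voxelization sweeps a sphere along each centerline (a capsule per
segment) and marks voxels at least half-covered, judged by 2×2×2 subvoxel
quadrature within the borderline shell; this keeps cylinder volumes and
lateral surfaces within ~10% of closed forms even at radii comparable to
the voxel pitch, where a center-point rule errs by 40% with grid-aligned
axes. Every voxel traversed by a true centerline is forced foreground.
The corruption model adds sub-threshold specks placed disjointly from the
vasculature, carves strictly interior single-voxel cavities, and flips
surface voxels symmetrically with a given probability.

What the phantoms do **not** emulate: real point-spread blur and intensity
inhomogeneity, learned-segmentation bias, vessel-wall thickness, flow
direction, arterial/venous identity, and the full degree heterogeneity of
real microvasculature (phantom degree tails are shorter; their γ and β
values are not calibrated to tissue values). Tests passing on phantoms
therefore validate the *measurement chain* — geometry, topology and
community statistics on known ground truth — not the biological fidelity
of any particular preset parameter.

Exact round-trip recovery (node count, edge count, degree multiset) is
guaranteed only under the stated preconditions — tube radius ≥ 1.5 voxels
and inter-segment clearance ≥ ~4 voxels — which the dedicated tree
fixtures satisfy; dense mesh phantoms intentionally violate clearance
(touching vessels merge, as in real segmentations), so their extracted
graphs differ from ground truth in controlled, realistic ways, including a
20–30% skeleton length deficit where junction clusters and merged tubes
swallow centerline.

## Problem sizes and determinism

Default test and demonstration volumes are 250–800 µm blocks (10⁵–10⁷
voxels, 10²–10⁴ graph nodes), which exercise every code path while keeping
the full suite in a few minutes; the random-graph baselines run at the
full printed size (358,000 nodes). All stochastic stages take explicit
integer seeds and no global random state is used anywhere, so any result
in the test suite, the acceptance script, or the pipeline is bit-for-bit
reproducible from its configuration.

## Known limitations

* Sub-voxel capillaries (radius below ~half the largest spacing) are
  rendered and measured at single-voxel thickness; absolute radiometric
  accuracy there is out of scope.
* The skeleton-based ρ_L systematically underestimates generative
  centerline length on dense networks (see above); comparisons across
  cohorts processed identically remain valid.
* Louvain is the only community method; modularity's resolution limit is
  inherited, and significance of Q is not assessed.
* The γ fit is the log-log least-squares convention, chosen for
  comparability, not the statistically efficient estimator.
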