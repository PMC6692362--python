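# vasculotopo

Geometric and graph-topological quantification of 3D cerebrovascular
networks from binary vessel volumes — the kind produced by light-sheet
(SPIM) imaging of perfusion-labelled mouse brain, where healthy tissue and
glioblastoma xenografts can be compared down to the capillary scale.

The package covers the full chain:

1. **Volume conditioning** — Gaussian smoothing with re-binarization,
   filling of enclosed cavities ("hollow" vessels), removal of isolated
   voxel bunches smaller than a 6 µm-radius sphere, region masking, and a
   skeleton-preserving circumferential thinning.
2. **Skeleton → graph** — 3D medial-axis thinning, voxel tagging
   (endpoint / slab / junction by 26-neighbour count), merging of
   26-connected junction clusters into branch nodes, and construction of an
   undirected spatial multigraph whose edges carry their centerline paths.
3. **Vessel geometry** — per-segment length *l*, endpoint separation *d*,
   tortuosity τ = *l*/*d* ≥ 1, distance-transform radius profiles *r̄*, and
   lateral surface area *A*; tissue-level fractional vessel volume *fVV* and
   microvascular density *MVD* on a 500 µm tiling; global densities
   ρ_L (mm/mm³) and ρ_A (mm²/mm³); correction of tissue-clearing shrinkage
   (linear factor 0.6^{1/3} ≈ 0.84 at 40% volume loss).
4. **Network topology** — degree distribution *P(k)* with power-law tail
   exponent γ (least squares on log–log axes for k ≥ 5), clustering
   coefficients C_i = 2E_i/(k_i(k_i−1)) with the hierarchical scaling
   exponent β from C_i(k_i) ∼ k_i^{−β}, characteristic path length *L* and
   diameter *D*, and Erdős–Rényi G(n, m) baseline ensembles.
5. **Community analysis** — Louvain modularity unfolding
   (Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j)) with all levels
   retained, per-community structure (nodes n, internal edges e, perimeter
   P, centroid, spatial extent R, community degree k_c = 2e + P), weighted
   meta-networks of communities, the isolation exponent ξ from P(e) ∼ e^ξ,
   the assortativity exponent κ from ⟨k_c1⟩(k_c) ∼ k_c^κ, and shortest path
   length versus centroid separation L_c(Δ).
6. **Cohort statistics** — Kruskal–Wallis comparisons over per-specimen
   summaries, plus a one-command pipeline with full provenance logging.

Because no public imaging data accompanies the study design this package
implements, it ships a first-class **synthetic phantom generator**: tube
networks on the anisotropic acquisition grid (3.25 × 3.25 × 5 µm) with known
ground-truth topology. The *healthy-like* preset combines bifurcating
arterio-venous trees (Murray-law radius tapering) with a capillary mesh
calibrated to ρ_L ≈ 980 mm/mm³ and ~11% endpoint nodes; the *tumor-like*
preset is sparser, endpoint-rich (~20%), more tortuous, fragmented, and
carries extra three-edge vessel loops. Pure graph generators (G(n, m),
deterministic hierarchical networks, configuration-model power laws) serve
as oracles for every statistical estimator.

## Worked example

Run the full pipeline on a simulated healthy-like tissue block
(520 × 520 × 400 µm at the default spacing):

```bash
vasculotopo run --mode healthy_like --seed 1 --out out/
```

Key lines of the printed report (abridged):

```json
{
  "geometry": {
    "fVV": 0.0489,
    "rho_L_mm_per_mm3": 692.3,
    "tortuosity_median": 1.147,
    "mean_radius_um": {"mean": 4.20, "dev_plus": 0.85, "dev_minus": 0.59}
  },
  "topology": {
    "n_nodes": 1332, "n_edges": 3066,
    "endpoint_fraction": 0.104, "k_max": 62,
    "mean_clustering": 0.139
  },
  "communities": {
    "Q": 0.835, "N_c": 18, "L_c": 1.69, "xi": 0.46
  }
}
```

Reading this: ~4.9% of the tissue volume is vessel lumen; the skeleton
carries 692 mm of centerline per mm³ (about 25–30% below the generative
980 mm/mm³, the expected deficit where the skeleton shortcuts merged tubes
and junction clusters); the median segment is mildly tortuous (τ̃ = 1.15);
10.4% of nodes are vessel endpoints, matching the healthy preset's target;
junction-cluster merging produces the heavy degree tail (k_max = 62); and
Louvain finds 18 strongly modular vessel communities (Q = 0.84) separated
by under two meta-hops on average.

The same library surface is available programmatically:

```python
import vasculotopo as vt
from vasculotopo import vessel_geometry as vg, topology_metrics as tm

truth = vt.generate_network(vt.healthy_like(seed=1))
vol = vt.voxelize(truth)
skel, graph = vt.extract_graph(vol)
segments = vg.segment_geometry(vol, graph)
topo = tm.summarize_topology(graph)
```

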