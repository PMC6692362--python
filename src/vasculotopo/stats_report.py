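"""Cohort comparison and the end-to-end analysis pipeline.

Group comparisons use the Kruskal–Wallis rank test (nonparametric one-way
ANOVA) on per-specimen summary values — the specimen, not the vessel, is the
unit of analysis, which avoids pseudoreplication across millions of
segments. No multiple-testing correction is applied; p-values are reported
per quantity as-is.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import community_analysis as ca
from . import skeleton_graph as sg
from . import synthetic_data as sd
from . import topology_metrics as tm
from . import vessel_geometry as vg
from . import volume_preprocess as vp


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p (g-1 dof).

    Degenerate input (all observations identical) yields (0.0, 1.0) rather
    than an error.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class CohortSummary:
    """Per-specimen summary records for one group (e.g. healthy-like)."""

    label: str
    records: pd.DataFrame  # one row per specimen, one column per quantity

    @property
    def n(self) -> int:
        return len(self.records)


def compare_cohorts(summaries: list[CohortSummary], quantities: list[str]) -> pd.DataFrame:
    """Group means +/- SD and Kruskal–Wallis p per quantity.

    Quantities absent from some cohort are skipped with a warning column
    entry; p is NaN when any group has a single specimen.
    """
    rows = []
    for q in quantities:
        row = {"quantity": q}
        samples = []
        ok = True
        for s in summaries:
            if q not in s.records.columns:
                ok = False
                continue
            vals = s.records[q].dropna().to_numpy(float)
            samples.append(vals)
            row[f"{s.label}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{s.label}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        if ok and len(samples) >= 2 and all(len(v) > 1 for v in samples):
            h, p = kruskal_wallis(samples)
            row["H"], row["p"] = h, p
        else:
            row["H"], row["p"] = np.nan, np.nan
            row["note"] = "skipped" if not ok else "insufficient specimens"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end phantom/analysis pipeline."""

    out_dir: str = "vasculotopo_out"
    input_tiff: str | None = None  # analyse an existing stack instead of simulating
    mask_tiff: str | None = None
    mode: str = "healthy_like"
    domain_size_um: tuple = (400.0, 520.0, 520.0)
    spacing_um: tuple = vp.DEFAULT_SPACING_UM
    seed: int = 0
    apply_noise: bool = False
    sigma_vox: float = 1.0
    speck_radius_um: float = 6.0
    box_um: float = 500.0
    gamma_k_min: int = 5
    beta_k_min: int = 3
    community_min_edges: int = 20
    delta_um: float = 50.0
    shrinkage_fraction: float = 0.40

    def spec(self) -> sd.PhantomSpec:
        maker = sd.healthy_like if self.mode == "healthy_like" else sd.tumor_like
        return maker(
            seed=self.seed,
            domain_size_um=self.domain_size_um,
            voxel_spacing_um=self.spacing_um,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate/ingest -> preprocess -> skeletonize -> graph -> geometry ->
    topology -> communities -> report.

    Writes per-stage CSV/JSON outputs plus a provenance record of every
    parameter and voxel count to ``out_dir``; deterministic given the config.
    Returns the result bundle in memory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in vars(config).items()}, "stages": []}

    if config.input_tiff:
        vol = vp.BinaryVolume.load_tiff(config.input_tiff, config.spacing_um)
        truth = None
    else:
        truth = sd.generate_network(config.spec())
        vol = sd.voxelize(truth)
        if config.apply_noise:
            vol = sd.corrupt(vol, sd.NoiseSpec(
                speck_count=20, hole_count=10, boundary_fuzz_prob=0.05,
                seed=config.seed + 1))
    mask = (
        vp.RegionMask(vp.BinaryVolume.load_tiff(config.mask_tiff, config.spacing_um).grid)
        if config.mask_tiff
        else None
    )

    # smoothing counteracts segmentation noise; on noise-free synthetic
    # volumes (exact tube widths) it would erode capillaries thinner than
    # the kernel, so it is applied only to noisy or file-based input
    if config.input_tiff or config.apply_noise:
        raw = vol
        vol = vp.smooth_and_rebinarize(vol, config.sigma_vox)
        provenance["stages"].append(vp.provenance_record(
            "smooth_and_rebinarize", raw, vol, sigma_vox=config.sigma_vox))
    prev = vol
    vol = vp.fill_holes(vol)
    provenance["stages"].append(vp.provenance_record("fill_holes", prev, vol))
    prev = vol
    vol = vp.remove_specks(vol, config.speck_radius_um)
    provenance["stages"].append(vp.provenance_record(
        "remove_specks", prev, vol, min_radius_um=config.speck_radius_um))
    if mask is not None:
        prev = vol
        vol = vp.apply_mask(vol, mask)
        provenance["stages"].append(vp.provenance_record("apply_mask", prev, vol))

    skel, graph = sg.extract_graph(vol)
    provenance["stages"].append({"step": "skeleton_graph", "params": {},
                                 "n_nodes": graph.n_nodes, "n_edges": graph.n_edges})
    graph.to_graphml(out / "graph.graphml")

    segments = vg.segment_geometry(vol, graph)
    tiles = vg.tile_stats(vol, graph, mask, box_um=config.box_um)
    densities = vg.global_densities(vol, graph, segments, mask)
    geometry_summary = vg.summarize_geometry(segments)
    vg.segments_table(segments).to_csv(out / "segments.csv", index=False)
    tiles.table.to_csv(out / "tiles.csv", index=False)

    topo = tm.summarize_topology(
        graph, gamma_k_min=config.gamma_k_min, beta_k_min=config.beta_k_min,
        seed=config.seed)

    partition = ca.louvain_unfold(graph, seed=config.seed)
    filtered, filter_log = ca.filter_isolated_communities(
        graph, partition.final, min_edges=config.community_min_edges)
    meta = ca.build_meta_network(graph, filtered, densities.tissue_volume_mm3)
    meta.records.to_csv(out / "communities.csv", index=False)
    meta_stats = ca.meta_topology(meta, seed=config.seed) if meta.n_communities >= 2 else None
    lc_delta = ca.path_length_vs_separation(meta, config.delta_um)
    lc_delta.to_csv(out / "path_length_vs_separation.csv", index=False)

    provenance["stages"].append({
        "step": "community_analysis",
        "params": {"min_edges": config.community_min_edges, "delta_um": config.delta_um,
                   "seed": config.seed},
        **filter_log,
    })
    provenance["thresholds"] = {
        "sigma_vox": config.sigma_vox,
        "speck_radius_um": config.speck_radius_um,
        "box_um": config.box_um,
        "gamma_k_min": config.gamma_k_min,
        "beta_k_min": config.beta_k_min,
        "community_min_edges": config.community_min_edges,
        "delta_um": config.delta_um,
        "shrinkage_fraction": config.shrinkage_fraction,
    }

    report = {
        "geometry": {
            "fVV": densities.fVV_global,
            "MVD_per_mm3": densities.MVD_global,
            "rho_L_mm_per_mm3": densities.rho_L,
            "rho_A_mm2_per_mm3": densities.rho_A,
            "tissue_volume_mm3": densities.tissue_volume_mm3,
            **geometry_summary,
        },
        "topology": {
            "n_nodes": topo.n_nodes,
            "n_edges": topo.n_edges,
            "node_density_per_mm3": sg.node_density(graph, densities.tissue_volume_mm3),
            "mean_degree": topo.mean_degree,
            "k_max": topo.k_max,
            "endpoint_fraction": graph.endpoint_fraction(),
            "gamma": topo.gamma.exponent,
            "mean_clustering": topo.mean_clustering,
            "beta": topo.beta.exponent,
            "path_length": topo.path_length,
            "diameter": topo.diameter,
        },
        "communities": {
            "Q": partition.q_final,
            "n_levels": len(partition.levels),
            "N_c": meta.n_communities,
            "N_ice": meta.n_intercommunity_edges,
            "rho_c_per_mm3": meta.rho_c,
            "rho_ice_per_mm3": meta.rho_ice,
            "mean_n": float(meta.records["n"].mean()) if len(meta.records) else np.nan,
            "mean_e": float(meta.records["e"].mean()) if len(meta.records) else np.nan,
            "mean_R_um": float(meta.records["R_um"].mean()) if len(meta.records) else np.nan,
            "mean_P": float(meta.records["P"].mean()) if len(meta.records) else np.nan,
            "xi": ca.fit_isolation_exponent(meta.records).exponent,
            "kappa": ca.fit_assortativity(meta).exponent,
            "C_c": meta_stats["C_c"] if meta_stats else np.nan,
            "L_c": meta_stats["L_c"] if meta_stats else np.nan,
            "D_c": meta_stats["D_c"] if meta_stats else np.nan,
            "mean_k_c_u": meta_stats["k_c_u_mean"] if meta_stats else np.nan,
        },
    }

    def _jsonable(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(type(x))

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=_jsonable))

    return {
        "volume": vol,
        "truth": truth,
        "skeleton": skel,
        "graph": graph,
        "segments": segments,
        "tiles": tiles,
        "densities": densities,
        "topology": topo,
        "partition": partition,
        "meta": meta,
        "report": report,
        "provenance": provenance,
    }
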