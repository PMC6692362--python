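"""Geometric quantification of vessel segments and tissue-level densities.

Per-segment measures: centerline length l (anisotropic physical step sum),
Euclidean endpoint separation d, tortuosity tau = l/d (the "distance metric",
>= 1 by construction), a centerline radius profile sampled from the Euclidean
distance transform, its mean r_bar, and the lateral surface area
A = sum 2 pi r_i dl_i.

Tissue-level measures: fractional vessel volume fVV and microvascular density
MVD on an isotropic tiling (default 500 um boxes), and global densities
rho_L (mm/mm^3) and rho_A (mm^2/mm^3). A shrinkage correction rescales
cleared-tissue measurements to in-vivo scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .skeleton_graph import VascularGraph
from .volume_preprocess import BinaryVolume, RegionMask


@dataclass
class SegmentGeometry:
    edge_id: tuple  # (u, v, key)
    length_um: float
    separation_um: float
    tortuosity: float  # NaN for self-loops (d == 0)
    mean_radius_um: float
    surface_area_um2: float
    radius_profile_um: np.ndarray


@dataclass
class TilingStats:
    box_um: float
    table: pd.DataFrame  # per box: iz, iy, ix, coverage, fVV, MVD
    n_boxes_total: int
    n_boxes_excluded: int

    @property
    def fvv(self) -> np.ndarray:
        return self.table["fVV"].to_numpy()

    @property
    def mvd(self) -> np.ndarray:
        return self.table["MVD"].to_numpy()


@dataclass
class DensitySummary:
    fVV_global: float
    MVD_global: float  # segments per mm^3
    rho_L: float  # mm / mm^3
    rho_A: float  # mm^2 / mm^3
    tissue_volume_mm3: float


def _mask_grid(vol: BinaryVolume, mask) -> np.ndarray:
    if mask is None:
        return np.ones(vol.grid.shape, bool)
    grid = mask.grid if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if grid.shape != vol.grid.shape:
        raise ValueError("mask shape does not match volume")
    return grid


def segment_geometry(vol: BinaryVolume, graph: VascularGraph) -> list[SegmentGeometry]:
    """Per-edge geometry from the binary volume and its extracted graph.

    The radius profile samples the anisotropic Euclidean distance transform at
    the interior (slab) voxels of each centerline; terminal junction-cluster
    voxels are excluded because their distance value conflates adjoining
    vessels. Edges with d = 0 (self-loops) get tau = NaN and are excluded from
    tortuosity statistics downstream.
    """
    spacing = vol.spacing_um
    edt = ndimage.distance_transform_edt(vol.grid, sampling=spacing)
    segments = []
    for u, v, k, d in graph.graph.edges(keys=True, data=True):
        path = np.asarray(d["path"], int)
        pts = path * spacing
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1) if len(pts) > 1 else np.array([])
        length = float(steps.sum())
        sep = float(np.linalg.norm(pts[-1] - pts[0]))
        tau = length / sep if sep > 0 else np.nan

        radii = edt[tuple(path.T)]
        interior = radii[1:-1] if len(radii) > 2 else radii
        interior = interior[interior > 0]
        profile = interior if interior.size else radii
        r_mean = float(profile.mean()) if profile.size else 0.0

        # local-cylinder lateral surface: per step, the mean of the two
        # endpoint radii (junction terminals fall back to the profile mean)
        r_for_area = radii.copy().astype(float)
        if len(r_for_area) > 2:
            r_for_area[0] = profile.mean() if profile.size else r_for_area[0]
            r_for_area[-1] = profile.mean() if profile.size else r_for_area[-1]
        if len(r_for_area) > 1:
            r_steps = 0.5 * (r_for_area[:-1] + r_for_area[1:])
            area = float((2 * np.pi * r_steps * steps).sum())
        else:
            area = 0.0
        segments.append(
            SegmentGeometry((u, v, k), length, sep, tau, r_mean, area, profile)
        )
    return segments


def tile_stats(
    vol: BinaryVolume,
    graph: VascularGraph | None = None,
    mask=None,
    box_um: float = 500.0,
    min_coverage: float = 0.5,
) -> TilingStats:
    """fVV and MVD on an isotropic tiling of the volume.

    Per box, fVV = foreground voxels / in-mask voxels and MVD = number of
    segments whose centerline median voxel falls in the box, per in-mask box
    volume in mm^3. Boxes with mask coverage below ``min_coverage`` are
    excluded.
    """
    spacing = vol.spacing_um
    nvox = np.maximum(1, np.round(box_um / spacing)).astype(int)
    if np.any(nvox < 2):
        raise ValueError(f"box of {box_um} um spans <2 voxels along some axis")
    m = _mask_grid(vol, mask)
    shape = np.asarray(vol.grid.shape)
    nboxes = np.ceil(shape / nvox).astype(int)

    # segment midpoints per box
    seg_counts = {}
    if graph is not None:
        for u, v, k, d in graph.graph.edges(keys=True, data=True):
            path = np.asarray(d["path"], int)
            mid = path[len(path) // 2]
            key = tuple(mid // nvox)
            seg_counts[key] = seg_counts.get(key, 0) + 1

    rows = []
    excluded = 0
    vox_mm3 = vol.voxel_volume_um3 * 1e-9
    for iz in range(nboxes[0]):
        for iy in range(nboxes[1]):
            for ix in range(nboxes[2]):
                sl = tuple(
                    slice(i * n, min((i + 1) * n, s))
                    for i, n, s in zip((iz, iy, ix), nvox, shape)
                )
                mbox = m[sl]
                in_mask = int(mbox.sum())
                coverage = in_mask / mbox.size
                if coverage < min_coverage or in_mask == 0:
                    excluded += 1
                    continue
                fg = int((vol.grid[sl] & mbox).sum())
                nseg = seg_counts.get((iz, iy, ix), 0)
                rows.append(
                    {
                        "iz": iz, "iy": iy, "ix": ix,
                        "coverage": coverage,
                        "fVV": fg / in_mask,
                        "MVD": nseg / (in_mask * vox_mm3),
                    }
                )
    table = pd.DataFrame(rows, columns=["iz", "iy", "ix", "coverage", "fVV", "MVD"])
    return TilingStats(box_um, table, int(np.prod(nboxes)), excluded)


def global_densities(
    vol: BinaryVolume,
    graph: VascularGraph | None,
    segments: list[SegmentGeometry],
    mask=None,
) -> DensitySummary:
    """rho_L = sum l / V, rho_A = sum A / V over the in-mask tissue volume."""
    m = _mask_grid(vol, mask)
    V = float(m.sum()) * vol.voxel_volume_um3 * 1e-9  # mm^3
    if V == 0:
        raise ValueError("mask volume is zero")
    total_l_mm = sum(s.length_um for s in segments) * 1e-3
    total_a_mm2 = sum(s.surface_area_um2 for s in segments) * 1e-6
    fvv = float((vol.grid & m).sum() / m.sum())
    return DensitySummary(
        fVV_global=fvv,
        MVD_global=len(segments) / V,
        rho_L=total_l_mm / V,
        rho_A=total_a_mm2 / V,
        tissue_volume_mm3=V,
    )


def scale_to_in_vivo(obj, shrinkage_fraction: float = 0.40):
    """Undo isotropic clearing shrinkage.

    A volume shrinkage of fraction s rescales lengths and radii by
    (1-s)^(-1/3), areas by (1-s)^(-2/3) and volumes by (1-s)^(-1); densities
    divide accordingly (e.g. rho_L by (1-s)^(-2/3)). Accepts a
    DensitySummary, a SegmentGeometry, or a list of SegmentGeometry.
    Negative fractions invert the correction (round-trip identity).
    """
    s = shrinkage_fraction
    if s >= 1:
        raise ValueError("shrinkage_fraction must be < 1")
    f = (1.0 - s) ** (-1.0 / 3.0)  # linear scale factor
    if isinstance(obj, list):
        return [scale_to_in_vivo(x, s) for x in obj]
    if isinstance(obj, SegmentGeometry):
        return _dc_replace(
            obj,
            length_um=obj.length_um * f,
            separation_um=obj.separation_um * f,
            mean_radius_um=obj.mean_radius_um * f,
            surface_area_um2=obj.surface_area_um2 * f**2,
            radius_profile_um=obj.radius_profile_um * f,
        )
    if isinstance(obj, DensitySummary):
        return DensitySummary(
            fVV_global=obj.fVV_global,
            MVD_global=obj.MVD_global / f**3,
            rho_L=obj.rho_L * f / f**3,
            rho_A=obj.rho_A * f**2 / f**3,
            tissue_volume_mm3=obj.tissue_volume_mm3 * f**3,
        )
    raise TypeError(f"cannot rescale {type(obj).__name__}")


def shrinkage_factors(shrinkage_fraction: float = 0.40) -> dict:
    """Linear scale factors of clearing shrinkage: cleared = in_vivo * f_down,
    in_vivo = cleared * f_up."""
    if not 0 <= shrinkage_fraction < 1:
        raise ValueError("shrinkage_fraction must be in [0, 1)")
    down = (1.0 - shrinkage_fraction) ** (1.0 / 3.0)
    return {"linear_down": down, "linear_up": 1.0 / down}


def summarize_geometry(segments: list[SegmentGeometry]) -> dict:
    """Cohort-style summary of segment geometry.

    Radii, lengths and areas (log-normally distributed in real vasculature)
    are reported as arithmetic means with average directed deviations: the
    mean deviation of values above the mean and below it, separately.
    Tortuosity (shifted-exponential) is reported as median and 95% quantile
    (linear interpolation between order statistics); self-loops are excluded
    and their count logged.
    """
    if not segments:
        raise ValueError("no segments")

    def directed(values):
        values = np.asarray(values, float)
        mu = values.mean()
        above = values[values > mu]
        below = values[values < mu]
        plus = float((above - mu).mean()) if above.size else 0.0
        minus = float((mu - below).mean()) if below.size else 0.0
        return {"mean": float(mu), "dev_plus": plus, "dev_minus": minus}

    taus = np.array([s.tortuosity for s in segments])
    n_undefined = int(np.isnan(taus).sum())
    taus = taus[~np.isnan(taus)]
    if n_undefined:
        warnings.warn(f"{n_undefined} self-loop segment(s) excluded from tortuosity stats")
    out = {
        "n_segments": len(segments),
        "mean_radius_um": directed([s.mean_radius_um for s in segments]),
        "length_um": directed([s.length_um for s in segments]),
        "surface_area_um2": directed([s.surface_area_um2 for s in segments]),
        "tortuosity_median": float(np.quantile(taus, 0.5)) if taus.size else np.nan,
        "tortuosity_q95": float(np.quantile(taus, 0.95)) if taus.size else np.nan,
        "n_tau_undefined": n_undefined,
    }
    return out


def segments_table(segments: list[SegmentGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "edge_id": [str(s.edge_id) for s in segments],
            "length_um": [s.length_um for s in segments],
            "separation_um": [s.separation_um for s in segments],
            "tortuosity": [s.tortuosity for s in segments],
            "mean_radius_um": [s.mean_radius_um for s in segments],
            "surface_area_um2": [s.surface_area_um2 for s in segments],
        }
    )
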