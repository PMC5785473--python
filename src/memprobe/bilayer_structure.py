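"""Bilayer structural observables: area per lipid and phosphate-peak thickness.

Area per lipid follows the tessellation approach: each lipid is represented
by the centroid of its three glycerol-region reference atoms (C2, C31, C21)
projected into the membrane plane, and its area is the cell of a periodic
Voronoi tessellation of those centroids.  By construction the cells tile the
leaflet, so per-leaflet areas sum exactly to the box cross-section.

Bilayer thickness is the peak-to-peak distance of the phosphorus mass
density along the membrane normal, with 3-point parabolic refinement of
each peak so the estimate does not quantize to the histogram bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from .trajectory_io import SelectionSet, Trajectory, frame_midplane

logger = logging.getLogger("memprobe")


@dataclass
class DensityProfile:
    """Mass density (amu/A^3) binned along z, bilayer center at 0."""

    bin_centers: np.ndarray
    density: np.ndarray
    label: str = ""
    bin_width: float = 0.2
    box_area: float = 0.0

    def total_mass_per_area(self) -> float:
        return float(self.density.sum() * self.bin_width)


@dataclass
class StructureSeries:
    """Per-frame area/thickness records plus a windowed summary."""

    time_ps: np.ndarray
    area_per_lipid: np.ndarray
    thickness: np.ndarray
    summary: dict


# ---------------------------------------------------------------------------

def assign_leaflets(coords: np.ndarray, selections: SelectionSet) -> dict:
    """Map each lipid key to 'upper'/'lower' by P position vs the midplane.

    A phosphorus exactly on the midplane goes to the upper leaflet with a
    warning.
    """
    mid = frame_midplane(coords, selections)
    out = {}
    for key, p_idx in selections.phosphorus.items():
        dz = coords[p_idx, 2] - mid
        if dz == 0.0:
            logger.warning("lipid %s has P exactly on the midplane; assigned upper", key)
        out[key] = "upper" if dz >= 0.0 else "lower"
    counts = {"upper": 0, "lower": 0}
    for v in out.values():
        counts[v] += 1
    if 0 in counts.values():
        logger.warning("one leaflet is empty: %s", counts)
    return out


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def periodic_voronoi_areas(points: np.ndarray, lx: float, ly: float) -> np.ndarray:
    """Voronoi cell area per point under periodic boundary conditions.

    Points are wrapped into [0, Lx) x [0, Ly) and replicated into the eight
    neighboring images before tessellating, which makes every central cell
    finite and equal to the true periodic cell; areas therefore sum to
    Lx * Ly exactly (to floating point).
    """
    pts = points.copy()
    pts[:, 0] %= lx
    pts[:, 1] %= ly
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to tessellate")
    shifts = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                       if (dx, dy) != (0, 0)])
    ghosts = (pts[None, :, :] + (shifts[:, None, :] * [lx, ly])).reshape(-1, 2)
    allpts = np.vstack([pts, ghosts])
    try:
        vor = Voronoi(allpts)
    except Exception as exc:
        raise ValueError(f"degenerate centroid set: {exc}") from exc
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise ValueError("unbounded Voronoi cell for a central point "
                             "(degenerate or collinear centroids)")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


def area_per_lipid(coords: np.ndarray, selections: SelectionSet,
                   leaflets: dict, box: tuple[float, float, float],
                   leaflet: str = "upper") -> tuple[dict, float]:
    """Per-lipid Voronoi areas (A^2) and the leaflet mean for one frame."""
    keys = [k for k in selections.lipid_keys if leaflets.get(k) == leaflet]
    if len(keys) < 3:
        raise ValueError(f"leaflet {leaflet!r} has {len(keys)} lipids; need >= 3")
    cent = np.array([coords[selections.glycerol_refs[k], :2].mean(axis=0)
                     for k in keys])
    areas = periodic_voronoi_areas(cent, box[0], box[1])
    return dict(zip(keys, areas)), float(areas.mean())


def mass_density_profile(trajectory: Trajectory, selections: SelectionSet,
                         masses: np.ndarray, indices: np.ndarray,
                         bin_width: float = 0.2, label: str = "") -> DensityProfile:
    """Frame-averaged mass density of the selected atoms along z.

    z is re-centered per frame to the bilayer midplane (mean phosphorus z);
    the histogram is normalized by bin volume (bin_width * Lx * Ly).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty selection for density profile")
    zmin, zmax = np.inf, -np.inf
    rel = []
    for coords in trajectory.frames:
        mid = frame_midplane(coords, selections)
        z = coords[indices, 2] - mid
        rel.append(z)
        zmin, zmax = min(zmin, z.min()), max(zmax, z.max())
    lo = np.floor(zmin / bin_width) * bin_width - bin_width
    hi = np.ceil(zmax / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    m = masses[indices]
    hist = np.zeros(edges.size - 1)
    area = 0.0
    for z, box in zip(rel, trajectory.boxes):
        hist += np.histogram(z, bins=edges, weights=m)[0]
        area += box[0] * box[1]
    area /= trajectory.n_frames
    density = hist / trajectory.n_frames / (bin_width * area)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(bin_centers=centers, density=density, label=label,
                          bin_width=bin_width, box_area=area)


def _refine_peak(centers: np.ndarray, density: np.ndarray, i: int) -> float:
    """3-point parabolic interpolation of the peak position around bin i."""
    if i == 0 or i == density.size - 1:
        return float(centers[i])
    y0, y1, y2 = density[i - 1], density[i], density[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(centers[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(centers[i] + np.clip(delta, -1, 1) * (centers[1] - centers[0]))


def bilayer_thickness(profile: DensityProfile) -> float:
    """Peak-to-peak distance (A) of the density profile across z = 0."""
    pos = profile.bin_centers > 0
    neg = profile.bin_centers < 0
    d = profile.density
    if d.std() == 0:
        raise ValueError("no peak: flat profile")
    if not pos.any() or not neg.any() or d[pos].max() <= 0 or d[neg].max() <= 0:
        raise ValueError("no peak on one side of the bilayer center")
    ip = np.flatnonzero(pos)[np.argmax(d[pos])]
    im = np.flatnonzero(neg)[np.argmax(d[neg])]
    zp = _refine_peak(profile.bin_centers, d, ip)
    zm = _refine_peak(profile.bin_centers, d, im)
    return zp - zm


def structure_series(trajectory: Trajectory, selections: SelectionSet,
                     masses: np.ndarray, bin_width: float = 0.2,
                     window_fraction: float = 1.0 / 3.0) -> StructureSeries:
    """Per-frame area per lipid (mean of both leaflets) and thickness.

    Thickness per frame comes from that frame's phosphorus density profile;
    the summary averages over the final `window_fraction` of frames
    (defaulting to the last third, the converged tail of a production run).
    """
    p_idx = selections.phosphorus_indices()
    areas, thicks = [], []
    for coords, box in zip(trajectory.frames, trajectory.boxes):
        leaflets = assign_leaflets(coords, selections)
        frame_areas = []
        for leaf in ("upper", "lower"):
            try:
                _, mean_a = area_per_lipid(coords, selections, leaflets, box, leaf)
                frame_areas.append(mean_a)
            except ValueError:
                pass
        if not frame_areas:
            raise ValueError("no leaflet with >= 3 lipids")
        areas.append(float(np.mean(frame_areas)))
        one = Trajectory(frames=[coords], boxes=[box],
                         frame_interval=trajectory.frame_interval)
        prof = mass_density_profile(one, selections, masses, p_idx,
                                    bin_width=bin_width, label="phosphorus")
        thicks.append(bilayer_thickness(prof))
    areas = np.array(areas)
    thicks = np.array(thicks)
    n0 = int(np.floor((1.0 - window_fraction) * len(areas)))
    summary = {
        "area_per_lipid_mean": float(areas[n0:].mean()),
        "area_per_lipid_sd": float(areas[n0:].std(ddof=1)) if len(areas) - n0 > 1 else 0.0,
        "thickness_mean": float(thicks[n0:].mean()),
        "thickness_sd": float(thicks[n0:].std(ddof=1)) if len(thicks) - n0 > 1 else 0.0,
        "window_frames": [n0, len(areas)],
    }
    return StructureSeries(time_ps=trajectory.times, area_per_lipid=areas,
                           thickness=thicks, summary=summary)
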