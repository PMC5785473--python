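"""Probe depth/tilt tracking and Boltzmann-inverted free-energy landscapes.

Each probe molecule contributes one (tilt, z) sample per frame: z is its
mass-weighted center of mass relative to the bilayer midplane, tilt the
angle between its ring-A -> ring-B axis and +z.  Pooled samples are binned
into a 2D histogram and converted to free energy by Boltzmann inversion,

    F(bin) = -kB T ln( p(bin) / p_max ),

so the most populated bin sits at F = 0 and empty bins are flagged as
unsampled rather than assigned a (divergent) finite energy.  1D profiles
along either axis marginalize the *probability* first and invert second,
which is the thermodynamically consistent order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import SelectionSet, Trajectory, frame_midplane

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)


@dataclass
class DepthTiltSample:
    molecule_id: int
    time_ps: float
    z_com: float    # A, bilayer center at 0
    tilt: float     # deg in [0, 180]


@dataclass
class FreeEnergyMap2D:
    angle_edges: np.ndarray   # deg
    z_edges: np.ndarray       # A
    counts: np.ndarray        # (n_angle, n_z)
    probability: np.ndarray
    free_energy: np.ndarray   # kcal/mol, NaN where unsampled
    unsampled: np.ndarray     # bool mask
    temperature: float        # K
    n_samples: int

    @property
    def angle_centers(self) -> np.ndarray:
        return 0.5 * (self.angle_edges[:-1] + self.angle_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def minimum_bin(self) -> tuple[float, float]:
        """(angle, z) center of the global free-energy minimum bin."""
        i, j = np.unravel_index(np.nanargmin(
            np.where(self.unsampled, np.nan, self.free_energy)), self.counts.shape)
        return float(self.angle_centers[i]), float(self.z_centers[j])


@dataclass
class Profile1D:
    centers: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    unsampled: np.ndarray
    axis: str

    def minimum(self) -> float:
        return float(self.centers[np.nanargmin(
            np.where(self.unsampled, np.nan, self.free_energy))])


# ---------------------------------------------------------------------------

def probe_depth_tilt_series(trajectory: Trajectory, selections: SelectionSet,
                            masses: np.ndarray) -> list[DepthTiltSample]:
    """One (z_com, tilt) sample per probe per frame."""
    if not selections.probe_axis:
        raise ValueError("no probe axis atoms resolved")
    samples = []
    keys = selections.probe_keys
    for fi, coords in enumerate(trajectory.frames):
        mid = frame_midplane(coords, selections)
        t = fi * trajectory.frame_interval
        for mi, key in enumerate(keys):
            idx = selections.probe_atoms[key]
            m = masses[idx]
            com_z = float((coords[idx, 2] * m).sum() / m.sum()) - mid
            ia, ib = selections.probe_axis[key]
            axis = coords[ib] - coords[ia]
            norm = np.linalg.norm(axis)
            if norm == 0:
                raise ValueError(f"probe {key}: degenerate axis")
            tilt = float(np.degrees(np.arccos(np.clip(axis[2] / norm, -1.0, 1.0))))
            samples.append(DepthTiltSample(molecule_id=mi, time_ps=t,
                                           z_com=com_z, tilt=tilt))
    return samples


def fold_lower_leaflet(samples: list[DepthTiltSample]) -> list[DepthTiltSample]:
    """Map lower-leaflet samples into the upper-leaflet frame.

    (z, tilt) -> (-z, 180 - tilt) for z < 0; valid by bilayer mirror
    symmetry and doubles the effective sampling of one map.
    """
    out = []
    for s in samples:
        if s.z_com < 0:
            out.append(DepthTiltSample(s.molecule_id, s.time_ps,
                                       -s.z_com, 180.0 - s.tilt))
        else:
            out.append(s)
    return out


def boltzmann_invert(prob: np.ndarray, temperature: float) -> tuple[np.ndarray, np.ndarray]:
    unsampled = prob <= 0
    fe = np.full(prob.shape, np.nan)
    pmax = prob.max()
    with np.errstate(divide="ignore"):
        fe[~unsampled] = -KB_KCAL * temperature * np.log(prob[~unsampled] / pmax)
    return fe, unsampled


def free_energy_map_2d(samples: list[DepthTiltSample],
                       angle_bin_width: float = 2.5, z_bin_width: float = 0.5,
                       temperature: float = 310.0,
                       angle_range: tuple[float, float] = (0.0, 180.0),
                       z_range: tuple[float, float] | None = None) -> FreeEnergyMap2D:
    """Bin (tilt, z) samples and Boltzmann-invert the 2D density."""
    if not samples:
        raise ValueError("no samples to histogram")
    if angle_bin_width <= 0 or z_bin_width <= 0:
        raise ValueError("bin widths must be positive")
    tilt = np.array([s.tilt for s in samples])
    z = np.array([s.z_com for s in samples])
    a_edges = np.arange(angle_range[0], angle_range[1] + angle_bin_width / 2,
                        angle_bin_width)
    if z_range is None:
        lo = np.floor(z.min() / z_bin_width) * z_bin_width
        hi = np.ceil(z.max() / z_bin_width) * z_bin_width
        if hi <= lo:
            hi = lo + z_bin_width
        z_range = (lo, hi)
    z_edges = np.arange(z_range[0], z_range[1] + z_bin_width / 2, z_bin_width)
    counts, _, _ = np.histogram2d(tilt, z, bins=[a_edges, z_edges])
    prob = counts / counts.sum()
    fe, unsampled = boltzmann_invert(prob, temperature)
    return FreeEnergyMap2D(angle_edges=a_edges, z_edges=z_edges, counts=counts,
                           probability=prob, free_energy=fe, unsampled=unsampled,
                           temperature=temperature, n_samples=len(samples))


def marginal_profile(fe_map: FreeEnergyMap2D, axis: str) -> Profile1D:
    """1D free energy along `axis` ('z' or 'angle'), other axis integrated out."""
    if axis not in ("z", "angle"):
        raise ValueError("axis must be 'z' or 'angle'")
    if axis == "z":
        prob = fe_map.probability.sum(axis=0)
        centers = fe_map.z_centers
    else:
        prob = fe_map.probability.sum(axis=1)
        centers = fe_map.angle_centers
    fe, unsampled = boltzmann_invert(prob, fe_map.temperature)
    return Profile1D(centers=centers, probability=prob, free_energy=fe,
                     unsampled=unsampled, axis=axis)
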