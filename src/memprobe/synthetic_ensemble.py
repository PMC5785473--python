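"""Seeded synthetic bilayer ensembles, assay readings, and thermograms.

This is a statistical emulator, not a force-field simulator: it places
idealized lipid and probe pseudo-atoms so that every downstream observable
(area per lipid, phosphate-peak thickness, per-carbon S_CD, probe depth/tilt
density, hydrogen-bond type frequencies) has a known planted ground truth.
Parameter-recovery tests against these plants are the package's primary
correctness evidence, since the reference trajectories they emulate are not
public.

Geometry conventions: the bilayer normal is z, the bilayer center is z = 0,
leaflets are mirror images.  Defaults emulate the studied system: 80 lipids
per leaflet, 18 probe molecules, ~52 A^2 per lipid and ~45 A phosphate
peak-to-peak thickness (gel-to-fluid transition regime at 310 K), probe
center of mass near z = 12 A tilted ~75 deg from the normal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .trajectory_io import (
    Atom,
    MolecularSystem,
    Trajectory,
    write_structure,
    write_trajectory,
)

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

#: Composite H-bond code frequencies used as planted defaults.  Chosen so
#: the per-probe-frame ensemble reproduces the headline bonding statistics
#: of the studied polyphenol/DPPC system: 1.6 H-bonds per probe on average,
#: 46.6% of events with ester carbonyl oxygens vs 53.4% with phosphate
#: oxygens, and the 3,5-dihydroxy end (To) dominating over the 4'-OH (B).
DEFAULT_HBOND_FREQUENCIES = {
    "NA": 0.10, "ToH": 0.19, "ToTa": 0.10, "ToTaH": 0.30,
    "BH": 0.0644, "BTa": 0.0456, "ToTaHBH": 0.10, "ToTaHBTa": 0.10,
}


@dataclass
class ProbeSpec:
    """Planted probe density: depth, tilt, and H-bond type frequencies."""

    n_probes: int = 18
    z_mean: float = 12.0        # A from bilayer center
    z_sigma: float = 1.5
    tilt_mean: float = 75.0     # deg from membrane normal
    tilt_sigma: float = 10.0
    hbond_type_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_HBOND_FREQUENCIES))
    sn2_fraction: float = 1.2 / 2.2  # share of planted ester bonds on sn-2

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if not (0.0 <= self.tilt_mean <= 180.0):
            raise ValueError("tilt_mean must lie in [0, 180] deg")
        total = sum(self.hbond_type_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"hbond_type_frequencies must sum to 1, got {total}")
        if any(p < 0 for p in self.hbond_type_frequencies.values()):
            raise ValueError("hbond_type_frequencies must be non-negative")


def _default_scd() -> dict:
    # Plateau-then-decay profile typical of a saturated acyl chain.
    prof = {}
    for chain in ("sn1", "sn2"):
        for c in range(2, 16):
            prof[(chain, c)] = round(0.21 if c <= 8 else 0.21 - 0.02 * (c - 8), 4)
    return prof


@dataclass
class EnsembleSpec:
    """Everything that defines a synthetic trajectory; ground truth echoes it."""

    n_lipids_per_leaflet: int = 80
    target_area_per_lipid: float = 51.7   # A^2
    target_thickness: float = 44.9        # A, P-peak to P-peak
    positional_noise_sigma: float = 0.5   # A
    n_frames: int = 100
    frame_interval: float = 2.0           # ps
    target_scd: dict = field(default_factory=_default_scd)
    probe_spec: ProbeSpec = field(default_factory=ProbeSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet <= 0 or self.n_frames <= 0:
            raise ValueError("counts must be positive")
        if self.target_area_per_lipid <= 0 or self.target_thickness <= 0:
            raise ValueError("area and thickness must be positive")
        for key, s in self.target_scd.items():
            if not (-1.0 <= s <= 0.5):
                raise ValueError(
                    f"target S_CD {s} for {key} outside the physical range [-1, +0.5]")

    @property
    def box_xy(self) -> float:
        """Box edge so that area/lipid is exact: L^2 = N * A."""
        return math.sqrt(self.n_lipids_per_leaflet * self.target_area_per_lipid)

    @property
    def box(self) -> tuple[float, float, float]:
        lz = self.target_thickness + 30.0  # headroom for probes above the leaflets
        return (self.box_xy, self.box_xy, lz)


# ---------------------------------------------------------------------------
# H-bond composite code grammar
# ---------------------------------------------------------------------------

DONOR_TOKENS = ("To", "B")       # 3,5-dihydroxy end; 4'-OH end
ACCEPTOR_TOKENS = ("Ta", "H")    # ester carbonyl O; phosphate O


def parse_hbond_code(code: str) -> dict[str, set[str]]:
    """Parse a composite code like 'ToTaH' into {donor: {acceptors}}.

    Grammar: donor sections in fixed order (To-part then B-part), each donor
    token followed by the acceptor tokens it bonds, Ta before H.  'NA' means
    no bond.
    """
    if code == "NA":
        return {}
    out: dict[str, set[str]] = {}
    i, cur = 0, None
    while i < len(code):
        if code.startswith("To", i):
            cur = "To"; out[cur] = set(); i += 2
        elif code.startswith("Ta", i):
            if cur is None:
                raise ValueError(f"code {code!r}: acceptor before any donor")
            out[cur].add("Ta"); i += 2
        elif code.startswith("B", i):
            cur = "B"; out[cur] = set(); i += 1
        elif code.startswith("H", i):
            if cur is None:
                raise ValueError(f"code {code!r}: acceptor before any donor")
            out[cur].add("H"); i += 1
        else:
            raise ValueError(f"unparseable H-bond code {code!r} at position {i}")
    if any(not acc for acc in out.values()):
        raise ValueError(f"code {code!r}: donor with no acceptor")
    return out


def format_hbond_code(bonds: dict[str, set[str]]) -> str:
    """Inverse of :func:`parse_hbond_code`: fixed To-then-B, Ta-then-H order."""
    if not bonds or all(not a for a in bonds.values()):
        return "NA"
    parts = []
    for donor in DONOR_TOKENS:
        acc = bonds.get(donor)
        if acc:
            parts.append(donor + "".join(t for t in ACCEPTOR_TOKENS if t in acc))
    return "".join(parts)


# ---------------------------------------------------------------------------
# S_CD-targeted C-H orientation sampling
# ---------------------------------------------------------------------------

def _scd_cone_weight(target: float) -> float:
    """Weight of the theta=0 cone in a {0 deg, 90 deg} mixture.

    S_CD = -1/2(3<cos^2 theta> - 1); with <cos^2> = w*1 + (1-w)*0 the weight
    solving the expectation is w = (1 - 2*S)/3, in [0, 1] exactly for
    S in [-1, +0.5].
    """
    w = (1.0 - 2.0 * target) / 3.0
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"target S_CD {target} infeasible")
    return w


def sample_ch_vectors(target: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n unit C-H vectors whose expected instantaneous S_CD is `target`."""
    w = _scd_cone_weight(target)
    axial = rng.random(n) < w
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    v = np.zeros((n, 3))
    v[axial, 2] = 1.0
    inplane = ~axial
    v[inplane, 0] = np.cos(phi[inplane])
    v[inplane, 1] = np.sin(phi[inplane])
    return v


# ---------------------------------------------------------------------------
# Bilayer ensemble
# ---------------------------------------------------------------------------

_BOND_OH = 0.96      # A, O-H
_BOND_OO = 2.80      # A, donor O ... acceptor O for a planted bond
_NA_CLEARANCE = 0.5  # A beyond the detection cutoff for planted non-bonds
_HB_CUTOFF = 3.5     # A, heavy-atom cutoff the plants are built against
_PROBE_AXIS_LEN = 8.0


def _probe_template() -> tuple[list[tuple[str, float]], np.ndarray]:
    """Rigid probe with axis along +z, COM at the origin.

    Atoms: RA/RB ring centroid markers 8 A apart, one O-H hydroxyl per end
    (O3/HO3 = 3,5-OH donor group on ring A, O4/HO4 = 4'-OH on ring B).
    """
    names = [("RA", 12.011), ("RB", 12.011), ("O3", 15.999), ("HO3", 1.008),
             ("O4", 15.999), ("HO4", 1.008)]
    h = _PROBE_AXIS_LEN / 2.0
    coords = np.array([
        [0.0, 0.0, -h],
        [0.0, 0.0, +h],
        [1.4, 0.0, -h],            # O3 off ring A
        [1.4 + _BOND_OH, 0.0, -h],  # HO3 pointing along +x
        [1.4, 0.0, +h],            # O4 off ring B
        [1.4 + _BOND_OH, 0.0, +h],
    ])
    masses = np.array([m for _, m in names])
    com = (coords * masses[:, None]).sum(0) / masses.sum()
    return names, coords - com


def _rotation_to(tilt_deg: float, azimuth: float) -> np.ndarray:
    """Rotation taking +z to the (tilt, azimuth) direction (R = Rz(phi)Ry(theta))."""
    t, p = math.radians(tilt_deg), azimuth
    ry = np.array([[math.cos(t), 0, math.sin(t)], [0, 1, 0],
                   [-math.sin(t), 0, math.cos(t)]])
    rz = np.array([[math.cos(p), -math.sin(p), 0],
                   [math.sin(p), math.cos(p), 0], [0, 0, 1]])
    return rz @ ry


def generate_bilayer_ensemble(
    spec: EnsembleSpec,
) -> tuple[MolecularSystem, Trajectory, dict]:
    """Build the synthetic system, trajectory, and ground-truth record.

    Per frame and leaflet, lipids sit on a jittered square lattice; the P
    atom of each lipid is at z = +/- thickness/2 plus Gaussian noise; the
    three glycerol reference atoms straddle the lattice site so their
    centroid is the site (jittered).  C-H bond vectors are drawn per carbon
    from the two-cone mixture matching the planted S_CD.  Probes are placed
    with Gaussian depth/tilt, alternating leaflets, and the lipid acceptor
    atoms nearest each probe are repositioned to realize the drawn H-bond
    code exactly (non-bonding acceptors stay > cutoff + 0.5 A away).
    """
    rng = np.random.default_rng(spec.seed)
    n_side = math.isqrt(spec.n_lipids_per_leaflet)
    if n_side * n_side != spec.n_lipids_per_leaflet:
        n_side = math.ceil(math.sqrt(spec.n_lipids_per_leaflet))
    box = spec.box
    spacing = box[0] / n_side

    # --- topology ---------------------------------------------------------
    carbons = sorted(spec.target_scd)  # (chain, index) keys
    atoms: list[Atom] = []
    lipid_atom_names: list[tuple[str, float]] = [
        ("P", 30.974), ("C2", 12.011), ("C31", 12.011), ("C21", 12.011),
        ("O13", 15.999), ("O14", 15.999), ("O22", 15.999), ("O32", 15.999),
    ]
    for chain, c in carbons:
        prefix = "C3" if chain == "sn1" else "C2"
        hs = ("X", "Y") if chain == "sn1" else ("R", "S")
        lipid_atom_names.append((f"{prefix}{c}", 12.011))
        lipid_atom_names.append((f"H{c}{hs[0]}", 1.008))
        lipid_atom_names.append((f"H{c}{hs[1]}", 1.008))
    n_lipids = 2 * spec.n_lipids_per_leaflet
    resid = 0
    for _ in range(n_lipids):
        resid += 1
        for name, mass in lipid_atom_names:
            atoms.append(Atom(name, "DPPC", resid, mass))
    probe_names, probe_template = _probe_template()
    for _ in range(spec.probe_spec.n_probes):
        resid += 1
        for name, mass in probe_names:
            atoms.append(Atom(name, "RESV", resid, mass))
    system = MolecularSystem(atoms=atoms, box=box)

    n_atoms_lipid = len(lipid_atom_names)
    n_lip_atoms = n_lipids * n_atoms_lipid
    half_z = spec.target_thickness / 2.0
    codes = list(spec.probe_spec.hbond_type_frequencies)
    code_p = np.array([spec.probe_spec.hbond_type_frequencies[c] for c in codes])

    # lattice sites, same for both leaflets
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    sites = (np.stack([gx.ravel(), gy.ravel()], axis=1)[: spec.n_lipids_per_leaflet]
             + 0.5) * spacing

    # acceptor offsets relative to the lipid lattice site (headgroup region,
    # placed BELOW the P plane toward the probes but still > cutoff away from
    # the default probe depth band)
    acc_roles = ["O13", "O14", "O22", "O32"]
    name_to_off = {n: i for i, (n, _) in enumerate(lipid_atom_names)}

    frames = []
    drawn_codes: list[list[str]] = []
    drawn_chains: list[list[dict]] = []
    for _ in range(spec.n_frames):
        coords = np.zeros((system.n_atoms, 3))
        for leaflet, zsign in ((0, +1.0), (1, -1.0)):
            base = leaflet * spec.n_lipids_per_leaflet * n_atoms_lipid
            jitter = rng.normal(0.0, spec.positional_noise_sigma,
                                (spec.n_lipids_per_leaflet, 2))
            xy = sites + jitter
            for li in range(spec.n_lipids_per_leaflet):
                a0 = base + li * n_atoms_lipid
                x, y = xy[li]
                pz = zsign * half_z + rng.normal(0.0, spec.positional_noise_sigma)
                coords[a0 + 0] = (x, y, pz)
                # glycerol refs straddle the site ~3 A below the P plane
                gz = zsign * (half_z - 3.0)
                coords[a0 + 1] = (x + 0.8, y, gz)
                coords[a0 + 2] = (x - 0.4, y + 0.7, gz)
                coords[a0 + 3] = (x - 0.4, y - 0.7, gz)
                # acceptors default to a shell above the P plane (away from
                # the probe depth band) so only repositioned ones can bond
                az = pz + zsign * 4.0
                coords[a0 + 4] = (x + 1.0, y + 1.0, az)   # O13
                coords[a0 + 5] = (x - 1.0, y + 1.0, az)   # O14
                coords[a0 + 6] = (x + 1.0, y - 1.0, az)   # O22 (sn-2 ester)
                coords[a0 + 7] = (x - 1.0, y - 1.0, az)   # O32 (sn-1 ester)
                # chain C-H pairs stacked below the glycerol region; both
                # hydrogens of a carbon draw independent orientation vectors
                for k, (chain, c) in enumerate(carbons):
                    cz = zsign * max(half_z - 4.0 - 1.2 * c, 1.0)
                    cpos = np.array([x, y, cz])
                    vecs = sample_ch_vectors(spec.target_scd[(chain, c)], 2, rng)
                    coords[a0 + 8 + 3 * k] = cpos
                    coords[a0 + 8 + 3 * k + 1] = cpos + 1.09 * vecs[0]
                    coords[a0 + 8 + 3 * k + 2] = cpos + 1.09 * vecs[1]

        # --- probes -------------------------------------------------------
        # probes live on their own sparse lateral lattice (per leaflet) so
        # no two probes can come within H-bond range of each other
        n_per_leaflet = (spec.probe_spec.n_probes + 1) // 2
        p_side = max(1, math.ceil(math.sqrt(n_per_leaflet)))
        p_spacing = box[0] / p_side
        frame_codes, frame_chains = [], []
        occupied = np.zeros(n_lipids, dtype=bool)
        for pi in range(spec.probe_spec.n_probes):
            p0 = n_lip_atoms + pi * len(probe_names)
            zsign = 1.0 if pi % 2 == 0 else -1.0
            slot = pi // 2
            z = rng.normal(spec.probe_spec.z_mean, spec.probe_spec.z_sigma)
            tilt = float(np.clip(
                rng.normal(spec.probe_spec.tilt_mean, spec.probe_spec.tilt_sigma),
                0.0, 180.0))
            x = (slot % p_side + 0.5) * p_spacing + rng.normal(0.0, 1.0)
            y = (slot // p_side + 0.5) * p_spacing + rng.normal(0.0, 1.0)
            if zsign < 0:
                z, tilt = -z, 180.0 - tilt
            rot = _rotation_to(tilt, rng.uniform(0.0, 2.0 * np.pi))
            pc = probe_template @ rot.T + np.array([x, y, z])
            coords[p0:p0 + len(probe_names)] = pc

            # plant the code with one neighboring lipid per bonded donor end
            # (each hydroxyl end bonds its own lipid, as the emulated system
            # shows); probes left without a free lipid stay unbonded
            code = codes[int(rng.choice(len(codes), p=code_p))]
            bonds = parse_hbond_code(code)
            chains: dict[str, str] = {}
            realized: dict[str, set] = {}
            leaflet_slice = (slice(0, spec.n_lipids_per_leaflet) if zsign > 0
                             else slice(spec.n_lipids_per_leaflet, n_lipids))
            lip_ids = np.arange(n_lipids)[leaflet_slice]
            all_sites = np.vstack([sites, sites])
            donor_atoms = {"To": (p0 + 2, p0 + 3), "B": (p0 + 4, p0 + 5)}
            for donor in DONOR_TOKENS:
                acceptors = bonds.get(donor)
                if not acceptors:
                    continue
                free = lip_ids[~occupied[lip_ids]]
                if free.size == 0:
                    continue
                d2 = ((all_sites[free] - [x, y]) ** 2).sum(1)
                target_lipid = int(free[np.argmin(d2)])
                occupied[target_lipid] = True
                a0 = target_lipid * n_atoms_lipid
                # park this lipid's acceptors well out of range first
                for role in acc_roles:
                    coords[a0 + name_to_off[role]] = (
                        coords[a0 + name_to_off["P"]]
                        + np.array([0.0, 0.0,
                                    np.sign(coords[a0 + name_to_off["P"], 2])
                                    * (_HB_CUTOFF + _NA_CLEARANCE + 1.0)]))
                oi, hi = donor_atoms[donor]
                oh = coords[hi] - coords[oi]
                oh /= np.linalg.norm(oh)
                perp = np.cross(oh, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-8:
                    perp = np.cross(oh, [1.0, 0.0, 0.0])
                perp /= np.linalg.norm(perp)
                for j, acc in enumerate(sorted(acceptors)):
                    # second acceptor 12 deg off-linear so the two do not
                    # coincide; D-H...A stays ~162 deg, inside the criterion
                    ang = 0.209 * j
                    direction = math.cos(ang) * oh + math.sin(ang) * perp
                    if acc == "H":
                        role = "O13"
                    else:
                        sn2 = rng.random() < spec.probe_spec.sn2_fraction
                        role = "O22" if sn2 else "O32"
                        chains[f"{donor}:Ta"] = "sn2" if role == "O22" else "sn1"
                    coords[a0 + name_to_off[role]] = (
                        coords[oi] + _BOND_OO * direction)
                    realized.setdefault(donor, set()).add(acc)
            frame_codes.append(format_hbond_code(realized))
            frame_chains.append(chains)
        frames.append(coords)
        drawn_codes.append(frame_codes)
        drawn_chains.append(frame_chains)

    traj = Trajectory(frames=frames, boxes=[box] * spec.n_frames,
                      frame_interval=spec.frame_interval)
    ground_truth = {
        "n_lipids_per_leaflet": spec.n_lipids_per_leaflet,
        "target_area_per_lipid": spec.target_area_per_lipid,
        "target_thickness": spec.target_thickness,
        "positional_noise_sigma": spec.positional_noise_sigma,
        "n_frames": spec.n_frames,
        "target_scd": {f"{c}:{i}": v for (c, i), v in spec.target_scd.items()},
        "probe": asdict(spec.probe_spec),
        "seed": spec.seed,
        "box": list(box),
        "planted_codes_per_frame": drawn_codes,
        "planted_ester_chains_per_frame": drawn_chains,
    }
    return system, traj, ground_truth


def write_ensemble(out_dir: str | Path, system: MolecularSystem,
                   trajectory: Trajectory, ground_truth: dict) -> dict[str, Path]:
    """Write PDB + DCD fixtures and ground_truth.json into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "structure": out / "system.pdb",
        "trajectory": out / "trajectory.dcd",
        "ground_truth": out / "ground_truth.json",
    }
    write_structure(paths["structure"], system, trajectory.frames[0])
    write_trajectory(paths["trajectory"], trajectory)
    paths["ground_truth"].write_text(json.dumps(ground_truth, indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Assay readings and thermograms
# ---------------------------------------------------------------------------

def generate_assay_readings(true_ffa: float, constants, noise_sigma: float = 0.0,
                            n: int = 1, seed: int = 0,
                            i457_scale: float = 1000.0) -> list:
    """Fluorescence readings whose noiseless intensity ratio encodes true_ffa.

    Inverts the binding equation [FFA] = Kd*Q*(R - R0)/(Rmax - R):
    R = (FFA*Rmax + Kd*Q*R0) / (FFA + Kd*Q).  Gaussian intensity noise is
    added independently per channel.
    """
    from .assay_quant import FluorescenceReading

    if true_ffa < 0:
        raise ValueError("true_ffa must be non-negative")
    kq = constants.Kd * constants.Q
    r0 = constants.R0_calibration
    rmax = constants.Rmax_calibration
    r = (true_ffa * rmax + kq * r0) / (true_ffa + kq)
    if r >= rmax:
        raise ValueError(f"true_ffa={true_ffa} implies R >= Rmax ({rmax}); saturated")
    rng = np.random.default_rng(seed)
    readings = []
    for k in range(n):
        i457 = i457_scale
        i550 = r * i457
        if noise_sigma > 0:
            i550 += rng.normal(0.0, noise_sigma)
            i457 += rng.normal(0.0, noise_sigma)
        readings.append(FluorescenceReading(
            sample_id=f"synthetic-{k}", I550=i550, I457=i457,
            I550_blank=0.0, I457_blank=0.0))
    return readings


def generate_thermogram(tm: float, half_height_width: float, amplitude: float = 1.0,
                        baseline_slope: float = 0.0, noise_sigma: float = 0.0,
                        grid: float = 0.02, seed: int = 0,
                        t_min: float | None = None, t_max: float | None = None,
                        pre_tm: float | None = None, pre_amplitude: float = 0.0,
                        pre_width: float = 1.0):
    """Gaussian endotherm on a linear baseline, optional pre-transition peak.

    half_height_width is the FWHM of the planted peak; sigma = FWHM /
    (2*sqrt(2 ln 2)).
    """
    from .assay_quant import Thermogram

    if half_height_width <= grid:
        raise ValueError("half_height_width must exceed the grid step")
    if t_min is None:
        t_min = tm - 8.0 * half_height_width
    if t_max is None:
        t_max = tm + 8.0 * half_height_width
    temps = np.arange(t_min, t_max + grid / 2, grid)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    sigma = half_height_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    heat = amplitude * np.exp(-0.5 * ((temps - tm) / sigma) ** 2)
    if pre_tm is not None and pre_amplitude > 0:
        psig = pre_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        heat = heat + pre_amplitude * np.exp(-0.5 * ((temps - pre_tm) / psig) ** 2)
    heat = heat + baseline_slope * (temps - temps[0])
    if noise_sigma > 0:
        heat = heat + np.random.default_rng(seed).normal(0.0, noise_sigma, temps.size)
    return Thermogram(temperature=temps, heat_flow=heat)
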