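"""Structure/trajectory input, role-based atom selections, and result output.

Structures are read from PDB files and trajectories from DCD or multi-model
PDB.  Atom selections are configured per residue type as named *roles*
(phosphorus, glycerol reference atoms, ester/phosphate oxygens, acyl C-H
pairs, probe hydroxyls and axis markers) and resolved once to 0-based atom
indices, so every downstream stage works on plain index arrays.

All coordinates are in Angstrom; boxes are orthorhombic (Lx, Ly, Lz).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("memprobe")

# Minimal element masses (amu) for the atom types bilayer analyses touch.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "X": 12.0,
}


class PDBParseError(ValueError):
    """Malformed PDB content; message names the offending line."""


class SelectionError(ValueError):
    """A selection role failed to resolve."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    residue_name: str
    residue_id: int
    mass: float


@dataclass
class MolecularSystem:
    """Static topology: atom records plus an optional orthorhombic box (A)."""

    atoms: list[Atom]
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("MolecularSystem needs at least one atom")
        if any(a.mass <= 0 for a in self.atoms):
            raise ValueError("all atom masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def residues(self) -> list[tuple[str, int, list[int]]]:
        """Contiguous (residue_name, residue_id, atom_indices) groups."""
        out: list[tuple[str, int, list[int]]] = []
        for i, a in enumerate(self.atoms):
            key = (a.residue_name, a.residue_id)
            if out and (out[-1][0], out[-1][1]) == key:
                out[-1][2].append(i)
            else:
                out.append((a.residue_name, a.residue_id, [i]))
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_atoms x 3, A), each with its own box."""

    frames: list[np.ndarray]
    boxes: list[tuple[float, float, float]]
    frame_interval: float = 2.0  # ps between stored frames

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory needs at least one frame")
        n = self.frames[0].shape[0]
        for k, (f, b) in enumerate(zip(self.frames, self.boxes)):
            if f.shape != (n, 3):
                raise ValueError(f"frame {k} has shape {f.shape}, expected ({n}, 3)")
            if any(x <= 0 for x in b):
                raise ValueError(f"frame {k} box must be positive, got {b}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# Default role -> atom-name mapping for CHARMM36 DPPC plus the synthetic
# two-ring probe.  Chain C-H pairs: palmitoyl carbons C22..C216 (sn-2) and
# C32..C316 (sn-1) with hydrogens H2R/H2S etc. are filled in lazily because
# fixture chains may cover any carbon subset.
DEFAULT_SELECTION_CONFIG: dict = {
    "DPPC": {
        "phosphorus": ["P"],
        "glycerol_refs": ["C2", "C31", "C21"],
        "ester_O_sn1": ["O32"],
        "ester_O_sn2": ["O22"],
        "phosphate_O": ["O13", "O14"],
        "chain_CH_pairs": {
            "sn1": {i: (f"C3{i}", [f"H{i}X", f"H{i}Y"]) for i in range(2, 16)},
            "sn2": {i: (f"C2{i}", [f"H{i}R", f"H{i}S"]) for i in range(2, 16)},
        },
    },
    "RESV": {
        "probe_oh_35": [("O3", "HO3")],
        "probe_oh_4p": [("O4", "HO4")],
        "probe_axis_ring_A": ["RA"],
        "probe_axis_ring_B": ["RB"],
    },
}


@dataclass
class SelectionSet:
    """Role selections resolved to 0-based atom indices.

    ``phosphorus`` maps lipid key -> index; ``glycerol_refs`` maps lipid key
    -> (3,) indices; acceptor roles map lipid key -> index list;
    ``chain_CH_pairs`` maps (chain, carbon) -> list over lipids of
    (C index, [H indices]); probe roles are keyed by probe residue key.
    A *key* is (residue_name, residue_id).
    """

    phosphorus: dict = field(default_factory=dict)
    glycerol_refs: dict = field(default_factory=dict)
    ester_O_sn1: dict = field(default_factory=dict)
    ester_O_sn2: dict = field(default_factory=dict)
    phosphate_O: dict = field(default_factory=dict)
    chain_CH_pairs: dict = field(default_factory=dict)
    probe_oh_35: dict = field(default_factory=dict)
    probe_oh_4p: dict = field(default_factory=dict)
    probe_axis: dict = field(default_factory=dict)
    probe_atoms: dict = field(default_factory=dict)
    excluded_lipids: list = field(default_factory=list)

    @property
    def lipid_keys(self) -> list:
        return sorted(self.glycerol_refs, key=lambda k: (k[1], k[0]))

    @property
    def probe_keys(self) -> list:
        return sorted(self.probe_axis, key=lambda k: (k[1], k[0]))

    def phosphorus_indices(self) -> np.ndarray:
        return np.array([self.phosphorus[k] for k in sorted(self.phosphorus, key=lambda k: (k[1], k[0]))], dtype=int)


# ---------------------------------------------------------------------------
# PDB / DCD reading
# ---------------------------------------------------------------------------

def _mass_from_name(name: str, element: str = "") -> float:
    sym = element.strip().capitalize() or name.strip()[:1].upper()
    if sym in ELEMENT_MASSES:
        return ELEMENT_MASSES[sym]
    raise PDBParseError(f"cannot assign a mass to atom name {name!r}")


def _validate_pdb_lines(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise PDBParseError(
                    f"{path}:{lineno}: truncated {rec} record (needs coordinate columns)")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(f"{path}:{lineno}: unparseable coordinates") from None


def load_structure(path: str | Path, format: str = "pdb") -> MolecularSystem:
    """Read a PDB file into a MolecularSystem, preserving atom order.

    The box is taken from the CRYST1 record when present.  Non-orthorhombic
    boxes (angles != 90 deg) are rejected.
    """
    import MDAnalysis as mda

    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="PDB")
    atoms = []
    for a in u.atoms:
        elem = getattr(a, "element", "") or ""
        atoms.append(Atom(a.name, a.resname, int(a.resid), _mass_from_name(a.name, elem)))
    box = None
    dims = u.dimensions
    if dims is not None and dims[:3].min() > 0:
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ValueError(f"non-orthorhombic box not supported (angles {dims[3:]})")
        box = (float(dims[0]), float(dims[1]), float(dims[2]))
    return MolecularSystem(atoms=atoms, box=box)


def load_trajectory(path: str | Path, system: MolecularSystem,
                    format: str | None = None, frame_interval: float = 2.0) -> Trajectory:
    """Read a DCD or multi-model PDB trajectory; coordinates in Angstrom."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "dcd"
    format = format.lower()
    if format not in ("dcd", "pdb"):
        raise ValueError(f"unsupported trajectory format {format!r}")
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty trajectory file")
    reader_cls = DCDReader if format == "dcd" else PDBReader
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = reader_cls(str(path))
    except Exception as exc:  # corrupt header etc.
        raise ValueError(f"{path}: cannot read {format} trajectory: {exc}") from exc
    if reader.n_atoms != system.n_atoms:
        raise ValueError(
            f"{path}: atom-count mismatch: trajectory has {reader.n_atoms}, "
            f"system has {system.n_atoms}")
    frames, boxes = [], []
    for ts in reader:
        frames.append(np.array(ts.positions, dtype=np.float64))
        dims = ts.dimensions
        if dims is None or dims[:3].min() <= 0:
            if system.box is None:
                raise ValueError(f"{path}: frame {len(frames)-1} has no box and system has none")
            boxes.append(system.box)
        else:
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise ValueError("non-orthorhombic box not supported")
            boxes.append((float(dims[0]), float(dims[1]), float(dims[2])))
    reader.close()
    if not frames:
        raise ValueError(f"{path}: trajectory contains no frames")
    return Trajectory(frames=frames, boxes=boxes, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Writing (fixtures and results)
# ---------------------------------------------------------------------------

def write_structure(path: str | Path, system: MolecularSystem,
                    coordinates: np.ndarray) -> None:
    """Write a single-frame PDB with CRYST1, element columns filled."""
    path = Path(path)
    lines = []
    if system.box is not None:
        lines.append("CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f P 1           1"
                     % (*system.box, 90.0, 90.0, 90.0))
    for i, (a, xyz) in enumerate(zip(system.atoms, coordinates), start=1):
        # element from the closest tabulated mass (names like RA are markers)
        elem = min(ELEMENT_MASSES, key=lambda s: abs(ELEMENT_MASSES[s] - a.mass))
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            "ATOM  %5d %-4s %-4s %4d    %8.3f%8.3f%8.3f  1.00  0.00          %2s"
            % (i % 100000, name[:4], a.residue_name[:4], a.residue_id % 10000,
               xyz[0], xyz[1], xyz[2], elem))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write frames to DCD (binary, float32)."""
    from MDAnalysis.coordinates.DCD import DCDWriter

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with DCDWriter(str(path), n_atoms=trajectory.n_atoms) as w:
            for coords, box in zip(trajectory.frames, trajectory.boxes):
                w.write(_FrameShim(coords, box))


class _FrameShim:
    """Duck-typed timestep for MDAnalysis writers."""

    def __init__(self, coords: np.ndarray, box: tuple[float, float, float]):
        from MDAnalysis.coordinates.timestep import Timestep

        ts = Timestep(coords.shape[0])
        ts.positions = coords.astype(np.float32)
        ts.dimensions = [box[0], box[1], box[2], 90.0, 90.0, 90.0]
        self.ts = ts
        self.universe = None

    def __getattr__(self, item):
        return getattr(self.ts, item)


def write_manifest(path: str | Path, subcommand: str, inputs: dict,
                   parameters: dict) -> dict:
    """Write a JSON run manifest recording everything that affects output."""
    import hashlib
    from datetime import datetime, timezone

    from . import __version__

    digest = {}
    for label, p in inputs.items():
        p = Path(p)
        digest[label] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None,
        }
    manifest = {
        "subcommand": subcommand,
        "inputs": digest,
        "parameters": parameters,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Selection resolution
# ---------------------------------------------------------------------------

def load_selection_config(path: str | Path) -> dict:
    """Read a selection config from YAML or JSON."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SelectionError(f"{path}: selection config must be a mapping")
    return cfg


def resolve_selections(system: MolecularSystem,
                       config: dict | None = None) -> SelectionSet:
    """Resolve role-based atom names to indices per residue.

    Lipids missing any glycerol reference atom are excluded with a warning;
    a role that resolves to zero atoms across *all* residues of its type is
    a configuration error.
    """
    if config is None:
        config = DEFAULT_SELECTION_CONFIG
    sel = SelectionSet()
    role_hits: dict[str, int] = {}

    for resname, resid, idxs in system.residues():
        rc = config.get(resname)
        if rc is None:
            continue
        key = (resname, resid)
        by_name: dict[str, list[int]] = {}
        for i in idxs:
            by_name.setdefault(system.atoms[i].name, []).append(i)

        def find(name: str) -> int | None:
            hits = by_name.get(name)
            return hits[0] if hits else None

        if "glycerol_refs" in rc:  # lipid residue
            refs = [find(n) for n in rc["glycerol_refs"]]
            if any(r is None for r in refs):
                missing = [n for n, r in zip(rc["glycerol_refs"], refs) if r is None]
                logger.warning("lipid %s %d missing glycerol ref atom(s) %s; excluded",
                               resname, resid, missing)
                sel.excluded_lipids.append(key)
                continue
            sel.glycerol_refs[key] = np.array(refs, dtype=int)
            role_hits["glycerol_refs"] = role_hits.get("glycerol_refs", 0) + 1
            for role in ("phosphorus", "ester_O_sn1", "ester_O_sn2", "phosphate_O"):
                names = rc.get(role, [])
                found = [find(n) for n in names]
                found = [f for f in found if f is not None]
                if found:
                    role_hits[role] = role_hits.get(role, 0) + 1
                if role == "phosphorus":
                    if found:
                        sel.phosphorus[key] = found[0]
                else:
                    getattr(sel, role)[key] = found
            for chain, carbons in rc.get("chain_CH_pairs", {}).items():
                for carbon, (cname, hnames) in carbons.items():
                    ci = find(cname)
                    if ci is None:
                        continue
                    his = [find(h) for h in hnames]
                    if any(h is None for h in his):
                        raise SelectionError(
                            f"lipid {resname} {resid}: carbon {cname} listed in "
                            f"chain_CH_pairs but hydrogen(s) missing")
                    sel.chain_CH_pairs.setdefault((chain, int(carbon)), []).append(
                        (ci, his))
                    role_hits["chain_CH_pairs"] = role_hits.get("chain_CH_pairs", 0) + 1
        elif "probe_axis_ring_A" in rc:  # probe residue
            ra = [find(n) for n in rc["probe_axis_ring_A"]]
            rb = [find(n) for n in rc["probe_axis_ring_B"]]
            if any(r is None for r in ra + rb):
                raise SelectionError(f"probe {resname} {resid}: axis atoms missing")
            sel.probe_axis[key] = (ra[0], rb[0])
            for r in ("probe_axis_ring_A", "probe_axis_ring_B"):
                role_hits[r] = role_hits.get(r, 0) + 1
            for role in ("probe_oh_35", "probe_oh_4p"):
                pairs = []
                for o_name, h_name in rc.get(role, []):
                    oi, hi = find(o_name), find(h_name)
                    if oi is None or hi is None:
                        raise SelectionError(
                            f"probe {resname} {resid}: hydroxyl {o_name}/{h_name} "
                            f"for role {role} missing")
                    pairs.append((oi, hi))
                if pairs:
                    role_hits[role] = role_hits.get(role, 0) + 1
                getattr(sel, role)[key] = pairs
            sel.probe_atoms[key] = np.array(idxs, dtype=int)

    # chain_CH_pairs is exempt: its carbon list is a template covering the
    # longest chain, and a fixture may legitimately carry a subset of carbons
    present = {rn for rn, _, _ in system.residues()}
    for resname, rc in config.items():
        if resname not in present:
            continue
        for role in rc:
            if role == "chain_CH_pairs":
                continue
            if rc.get(role) and role_hits.get(role, 0) == 0:
                raise SelectionError(
                    f"role {role!r} for residue type {resname!r} resolved to "
                    f"0 atoms (misspelled atom name?)")
    return sel


def frame_midplane(coords: np.ndarray, selections: SelectionSet) -> float:
    """Bilayer midplane z: mean z of all phosphorus atoms."""
    p_idx = selections.phosphorus_indices()
    if p_idx.size == 0:
        raise SelectionError("no phosphorus atoms resolved")
    return float(coords[p_idx, 2].mean())
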