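"""Deuterium order parameters S_CD for the acyl chains.

S_CD = -1/2 <3 cos^2(theta) - 1>, where theta is the instantaneous angle
between a C-H bond and the bilayer normal (fixed to z) and the average runs
over frames, lipids, and the equivalent hydrogens of each carbon.  The
value is bounded: -1 (bond parallel to the normal) to +1/2 (perpendicular);
an isotropic orientation distribution gives 0.  Chains follow the usual
glycerolipid convention: sn-2 is the tail on the oxygen of the glycerol
second carbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import SelectionSet, Trajectory

NORMAL_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class OrderParameterProfile:
    records: list  # of dicts: chain, carbon, scd, stderr

    def as_rows(self) -> list[dict]:
        return list(self.records)

    def value(self, chain: str, carbon: int) -> float:
        for r in self.records:
            if r["chain"] == chain and r["carbon"] == carbon:
                return r["scd"]
        raise KeyError((chain, carbon))


def scd_instant(ch_vector: np.ndarray, normal: np.ndarray = NORMAL_Z) -> float:
    """Instantaneous -1/2(3cos^2 theta - 1) for one C-H vector."""
    v = np.asarray(ch_vector, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("zero-length C-H vector")
    c = np.dot(v, normal) / (norm * np.linalg.norm(normal))
    return -0.5 * (3.0 * c * c - 1.0)


def scd_from_vectors(vectors: np.ndarray) -> float:
    """Mean S_CD over an (n, 3) array of C-H vectors."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-length C-H vector")
    c2 = (v[:, 2] / norms) ** 2
    return float(np.mean(-0.5 * (3.0 * c2 - 1.0)))


def scd_profile(trajectory: Trajectory, selections: SelectionSet,
                n_blocks: int = 5) -> OrderParameterProfile:
    """Per-carbon S_CD averaged over frames, lipids and hydrogens.

    The standard error comes from `n_blocks` contiguous frame blocks
    (block means treated as independent), the usual correction for
    time-correlated trajectory data.
    """
    if not selections.chain_CH_pairs:
        raise ValueError("no chain C-H pairs resolved")
    records = []
    n_frames = trajectory.n_frames
    n_blocks = max(1, min(n_blocks, n_frames))
    bounds = np.linspace(0, n_frames, n_blocks + 1).astype(int)
    for (chain, carbon) in sorted(selections.chain_CH_pairs):
        pairs = selections.chain_CH_pairs[(chain, carbon)]
        frame_means = np.empty(n_frames)
        for fi, coords in enumerate(trajectory.frames):
            vals = []
            for ci, his in pairs:
                for hi in his:
                    v = coords[hi] - coords[ci]
                    n = np.linalg.norm(v)
                    if n == 0:
                        raise ValueError(
                            f"zero-length C-H vector at chain {chain} carbon {carbon}")
                    c2 = (v[2] / n) ** 2
                    vals.append(-0.5 * (3.0 * c2 - 1.0))
            frame_means[fi] = np.mean(vals)
        block_means = np.array([frame_means[a:b].mean()
                                for a, b in zip(bounds[:-1], bounds[1:]) if b > a])
        stderr = (float(block_means.std(ddof=1) / np.sqrt(block_means.size))
                  if block_means.size > 1 else 0.0)
        records.append({"chain": chain, "carbon": carbon,
                        "scd": float(frame_means.mean()),
                        "abs_scd": abs(float(frame_means.mean())),
                        "stderr": stderr})
    return OrderParameterProfile(records=records)
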