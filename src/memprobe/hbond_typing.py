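"""Geometric probe-lipid hydrogen-bond detection and composite-code typing.

A hydrogen bond is declared when the donor-acceptor heavy-atom (O...O)
distance is at most `d_max` (default 3.5 A) and the D-H...A angle is at
least `angle_min` (default 150 deg), under minimum-image convention.  Only
the probe donates: its 3,5-dihydroxy end ("To") and its 4'-OH ("B") are the
donor groups; lipid phosphate oxygens ("H") and ester carbonyl oxygens
("Ta", carrying an sn-1/sn-2 chain label) are the acceptors.

Each (probe, frame) is classified into a composite code concatenating the
donor tokens with the acceptor tokens they touch (To-part then B-part, Ta
before H): ToH, ToTa, ToTaH, BH, ..., or NA when no bond exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_ensemble import format_hbond_code
from .trajectory_io import SelectionSet, Trajectory

DEFAULT_D_MAX = 3.5       # A, donor-acceptor heavy-atom cutoff
DEFAULT_ANGLE_MIN = 150.0  # deg, D-H...A


@dataclass(frozen=True)
class HBondEvent:
    frame: int
    probe_id: int
    donor_group: str     # "To" or "B"
    acceptor_group: str  # "H" (phosphate O) or "Ta" (ester carbonyl O)
    lipid_id: int
    ester_chain: str     # "sn1"/"sn2" for Ta, "none" for H

    def __post_init__(self):
        if (self.acceptor_group == "Ta") != (self.ester_chain != "none"):
            raise ValueError("ester_chain must be set iff acceptor is an ester O")


@dataclass
class HBondTypeTable:
    probabilities: dict          # composite code -> probability
    mean_hbonds_per_probe: float
    frac_ester: float
    frac_phosphate: float
    sn2_to_sn1_ratio: float | None  # None when no sn-1 ester events


def _minimum_image(d: np.ndarray, box: tuple[float, float, float]) -> np.ndarray:
    b = np.asarray(box)
    return d - b * np.round(d / b)


def detect_hbonds(coords: np.ndarray, frame_index: int, selections: SelectionSet,
                  box: tuple[float, float, float],
                  d_max: float = DEFAULT_D_MAX,
                  angle_min: float = DEFAULT_ANGLE_MIN) -> list[HBondEvent]:
    """All probe->lipid hydrogen bonds in one frame."""
    # acceptor table: (atom index, token, lipid ordinal, chain)
    acceptors: list[tuple[int, str, int, str]] = []
    for li, key in enumerate(selections.lipid_keys):
        for idx in selections.phosphate_O.get(key, []):
            acceptors.append((idx, "H", li, "none"))
        for idx in selections.ester_O_sn1.get(key, []):
            acceptors.append((idx, "Ta", li, "sn1"))
        for idx in selections.ester_O_sn2.get(key, []):
            acceptors.append((idx, "Ta", li, "sn2"))
    if not acceptors:
        raise ValueError("no lipid acceptor atoms resolved")
    acc_idx = np.array([a[0] for a in acceptors])
    acc_pos = coords[acc_idx]
    cos_min = np.cos(np.radians(180.0 - angle_min))  # cos of max deviation

    events = []
    for pi, key in enumerate(selections.probe_keys):
        for donor_group, pairs in (("To", selections.probe_oh_35.get(key, [])),
                                   ("B", selections.probe_oh_4p.get(key, []))):
            for oi, hi in pairs:
                d_o = coords[oi]
                d_h = coords[hi]
                sep = _minimum_image(acc_pos - d_o, box)
                dist = np.linalg.norm(sep, axis=1)
                close = dist <= d_max
                if not close.any():
                    continue
                oh = _minimum_image(d_h - d_o, box)
                for ai in np.flatnonzero(close):
                    ha = _minimum_image(acc_pos[ai] - d_h, box)
                    nh, na = np.linalg.norm(oh), np.linalg.norm(ha)
                    if nh == 0 or na == 0:
                        continue
                    # D-H...A angle: cos(angle at H between H->D and H->A);
                    # angle >= angle_min  <=>  H->A within (180-angle_min) of D->H
                    cosdev = float(np.dot(oh, ha) / (nh * na))
                    if cosdev >= cos_min:
                        _, token, li, chain = acceptors[ai]
                        events.append(HBondEvent(frame=frame_index, probe_id=pi,
                                                 donor_group=donor_group,
                                                 acceptor_group=token,
                                                 lipid_id=li, ester_chain=chain))
    return events


def detect_hbonds_trajectory(trajectory: Trajectory, selections: SelectionSet,
                             d_max: float = DEFAULT_D_MAX,
                             angle_min: float = DEFAULT_ANGLE_MIN) -> list[HBondEvent]:
    events = []
    for fi, (coords, box) in enumerate(zip(trajectory.frames, trajectory.boxes)):
        events.extend(detect_hbonds(coords, fi, selections, box, d_max, angle_min))
    return events


def classify_probe_frame(events: list[HBondEvent]) -> str:
    """Composite code for one probe in one frame ('NA' when no events)."""
    if not events:
        return "NA"
    ref = (events[0].probe_id, events[0].frame)
    bonds: dict[str, set[str]] = {}
    for e in events:
        if (e.probe_id, e.frame) != ref:
            raise ValueError("events from mixed probes/frames")
        bonds.setdefault(e.donor_group, set()).add(e.acceptor_group)
    return format_hbond_code(bonds)


def hbond_statistics(events: list[HBondEvent], n_probes: int,
                     n_frames: int) -> HBondTypeTable:
    """Code probabilities over probe-frames plus event-level summaries."""
    if n_probes < 1 or n_frames < 1:
        raise ValueError("n_probes and n_frames must be >= 1")
    by_pf: dict[tuple[int, int], list[HBondEvent]] = {}
    for e in events:
        by_pf.setdefault((e.probe_id, e.frame), []).append(e)
    total_pf = n_probes * n_frames
    counts: dict[str, int] = {}
    for evs in by_pf.values():
        code = classify_probe_frame(evs)
        counts[code] = counts.get(code, 0) + 1
    counts["NA"] = counts.get("NA", 0) + (total_pf - len(by_pf))
    probs = {c: n / total_pf for c, n in sorted(counts.items())}

    n_events = len(events)
    n_ester = sum(1 for e in events if e.acceptor_group == "Ta")
    n_phos = n_events - n_ester
    n_sn1 = sum(1 for e in events if e.ester_chain == "sn1")
    n_sn2 = sum(1 for e in events if e.ester_chain == "sn2")
    return HBondTypeTable(
        probabilities=probs,
        mean_hbonds_per_probe=n_events / total_pf,
        frac_ester=n_ester / n_events if n_events else 0.0,
        frac_phosphate=n_phos / n_events if n_events else 0.0,
        sn2_to_sn1_ratio=(n_sn2 / n_sn1) if n_sn1 else None,
    )
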