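import math
from collections import Counter

import numpy as np
import pytest

import memprobe as mp
from memprobe.hbond_typing import HBondEvent, detect_hbonds
from memprobe.trajectory_io import SelectionSet


def _toy_selections():
    """Two probes (one O-H donor per group) + two lipids with 4 acceptors.

    Atom layout: [O3, HO3, O4, HO4] x2 probes, then [O13, O14, O22, O32] x2
    lipids -> 16 atoms.
    """
    sel = SelectionSet()
    for p in range(2):
        key = ("RESV", 100 + p)
        base = 4 * p
        sel.probe_oh_35[key] = [(base + 0, base + 1)]
        sel.probe_oh_4p[key] = [(base + 2, base + 3)]
        sel.probe_axis[key] = (base + 0, base + 2)
        sel.probe_atoms[key] = np.arange(base, base + 4)
    for li in range(2):
        key = ("DPPC", 1 + li)
        base = 8 + 4 * li
        sel.glycerol_refs[key] = np.array([base, base + 1, base + 2])
        sel.phosphate_O[key] = [base + 0, base + 1]
        sel.ester_O_sn2[key] = [base + 2]
        sel.ester_O_sn1[key] = [base + 3]
    return sel


BOX = (50.0, 50.0, 50.0)


def _coords_far():
    rng = np.random.default_rng(0)
    c = rng.uniform(20, 30, (16, 3))
    c[0::4] += np.arange(4)[:, None] * 0  # noqa: keep deterministic layout
    # spread everything far apart
    return np.arange(16)[:, None] * 3.0 + np.array([5.0, 5.0, 5.0])


def test_ideal_geometry_is_one_event():
    sel = _toy_selections()
    coords = _coords_far()
    coords[0] = [10.0, 10.0, 10.0]        # donor O (To of probe 0)
    coords[1] = [10.96, 10.0, 10.0]       # H along +x
    coords[8] = [12.8, 10.0, 10.0]        # lipid 0 phosphate O at 2.8 A, 180 deg
    events = detect_hbonds(coords, 0, sel, BOX)
    assert len(events) == 1
    e = events[0]
    assert (e.donor_group, e.acceptor_group, e.lipid_id, e.ester_chain) == \
        ("To", "H", 0, "none")


def test_beyond_distance_cutoff_is_no_event():
    sel = _toy_selections()
    coords = _coords_far()
    coords[0] = [10.0, 10.0, 10.0]
    coords[1] = [10.96, 10.0, 10.0]
    coords[8] = [14.0, 10.0, 10.0]  # 4.0 A > 3.5
    assert detect_hbonds(coords, 0, sel, BOX) == []


def test_bent_geometry_below_angle_cutoff_is_no_event():
    sel = _toy_selections()
    coords = _coords_far()
    coords[0] = [10.0, 10.0, 10.0]
    coords[1] = [10.96, 10.0, 10.0]
    # 2.8 A away but at 90 deg from the O-H direction
    coords[8] = [10.0, 12.8, 10.0]
    assert detect_hbonds(coords, 0, sel, BOX) == []


def _brute_force(coords, sel, box, d_max=3.5, angle_min=150.0):
    """All-pairs reference detector with explicit minimum-image arithmetic."""
    def mic(v):
        return v - np.array(box) * np.round(v / np.array(box))

    events = []
    for pi, key in enumerate(sel.probe_keys):
        for dg, pairs in (("To", sel.probe_oh_35.get(key, [])),
                          ("B", sel.probe_oh_4p.get(key, []))):
            for oi, hi in pairs:
                for li, lkey in enumerate(sel.lipid_keys):
                    pools = [(sel.phosphate_O.get(lkey, []), "H", "none"),
                             (sel.ester_O_sn1.get(lkey, []), "Ta", "sn1"),
                             (sel.ester_O_sn2.get(lkey, []), "Ta", "sn2")]
                    for idxs, token, chain in pools:
                        for ai in idxs:
                            if np.linalg.norm(mic(coords[ai] - coords[oi])) > d_max:
                                continue
                            oh = mic(coords[hi] - coords[oi])
                            ha = mic(coords[ai] - coords[hi])
                            cosang = np.dot(-oh, ha) / (
                                np.linalg.norm(oh) * np.linalg.norm(ha))
                            # angle at H between H->D and H->A is D-H...A
                            ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                            if ang >= angle_min:
                                events.append((pi, dg, token, li, chain))
    return sorted(events)


def test_detector_matches_brute_force_on_random_frames():
    sel = _toy_selections()
    rng = np.random.default_rng(99)
    n_hits = 0
    for fi in range(200):
        coords = rng.uniform(0, 7.0, (16, 3))  # dense: plenty of contacts
        for oi, hi in ((0, 1), (2, 3), (4, 5), (6, 7)):
            u = rng.normal(size=3)
            coords[hi] = coords[oi] + 0.96 * u / np.linalg.norm(u)
        got = sorted((e.probe_id, e.donor_group, e.acceptor_group, e.lipid_id,
                      e.ester_chain)
                     for e in detect_hbonds(coords, fi, sel, BOX))
        ref = _brute_force(coords, sel, BOX)
        assert got == ref
        n_hits += len(ref)
    assert n_hits > 20  # the comparison actually exercised events


def test_detector_invariant_under_rotation_and_translation():
    sel = _toy_selections()
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 12.0, (16, 3))
    big_box = (500.0, 500.0, 500.0)  # avoid wrap effects under rotation
    ref = sorted((e.donor_group, e.acceptor_group, e.lipid_id)
                 for e in detect_hbonds(coords, 0, sel, big_box))
    th = 0.7
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    moved = coords @ rot.T + np.array([30.0, -12.0, 7.0])
    got = sorted((e.donor_group, e.acceptor_group, e.lipid_id)
                 for e in detect_hbonds(moved, 0, sel, big_box))
    assert got == ref


def _ev(donor, acc, chain="none", probe=0, frame=0, lipid=0):
    return HBondEvent(frame=frame, probe_id=probe, donor_group=donor,
                      acceptor_group=acc, lipid_id=lipid, ester_chain=chain)


def test_classification_codes():
    assert mp.classify_probe_frame([]) == "NA"
    assert mp.classify_probe_frame([_ev("To", "H")]) == "ToH"
    assert mp.classify_probe_frame([_ev("To", "Ta", "sn2")]) == "ToTa"
    assert mp.classify_probe_frame(
        [_ev("To", "Ta", "sn1"), _ev("To", "H")]) == "ToTaH"
    assert mp.classify_probe_frame([_ev("B", "H")]) == "BH"
    assert mp.classify_probe_frame(
        [_ev("To", "H"), _ev("B", "Ta", "sn2")]) == "ToHBTa"


def test_mixed_probe_events_rejected():
    with pytest.raises(ValueError, match="mixed"):
        mp.classify_probe_frame([_ev("To", "H", probe=0),
                                 _ev("B", "H", probe=1)])


def test_event_invariant_chain_vs_acceptor():
    with pytest.raises(ValueError):
        _ev("To", "H", chain="sn1")
    with pytest.raises(ValueError):
        _ev("To", "Ta", chain="none")


def test_statistics_arithmetic():
    events = ([_ev("To", "Ta", "sn2", frame=f) for f in range(6)]
              + [_ev("To", "Ta", "sn1", frame=f, probe=1) for f in range(5)])
    table = mp.hbond_statistics(events, n_probes=2, n_frames=6)
    assert table.sn2_to_sn1_ratio == pytest.approx(1.2)
    assert table.frac_ester == 1.0 and table.frac_phosphate == 0.0
    assert table.mean_hbonds_per_probe == pytest.approx(11 / 12)
    assert sum(table.probabilities.values()) == pytest.approx(1.0)
    # NA probability = fraction of probe-frames without events
    assert table.probabilities["NA"] == pytest.approx(1 / 12)


def test_two_events_everywhere_gives_mean_two():
    events = [_ev("To", "H", probe=p, frame=f) for p in range(3)
              for f in range(4)] + \
             [_ev("B", "Ta", "sn2", probe=p, frame=f) for p in range(3)
              for f in range(4)]
    table = mp.hbond_statistics(events, n_probes=3, n_frames=4)
    assert table.mean_hbonds_per_probe == 2.0


def test_zero_sn1_events_gives_undefined_ratio():
    table = mp.hbond_statistics([_ev("To", "Ta", "sn2")], 1, 1)
    assert table.sn2_to_sn1_ratio is None


def test_planted_code_frequencies_recovered_end_to_end():
    freqs = {"NA": 0.3, "ToH": 0.4, "BH": 0.3}
    spec = mp.EnsembleSpec(
        n_lipids_per_leaflet=16, n_frames=100, seed=17, target_scd={},
        probe_spec=mp.ProbeSpec(n_probes=10, hbond_type_frequencies=freqs))
    system, traj, truth = mp.generate_bilayer_ensemble(spec)
    sel = mp.resolve_selections(system)
    events = mp.detect_hbonds_trajectory(traj, sel)
    table = mp.hbond_statistics(events, len(sel.probe_keys), traj.n_frames)
    planted = Counter(c for fr in truth["planted_codes_per_frame"] for c in fr)
    n_pf = spec.probe_spec.n_probes * spec.n_frames
    # detector+classifier reproduce the realized plants exactly
    for code, cnt in planted.items():
        assert table.probabilities.get(code, 0.0) == pytest.approx(cnt / n_pf)
    # and the realized plants match the requested frequencies statistically
    for code, p in freqs.items():
        assert planted[code] / n_pf == pytest.approx(p, abs=0.02)
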