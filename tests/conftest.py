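import numpy as np
import pytest

import memprobe as mp


@pytest.fixture(scope="session")
def small_ensemble():
    """Jittered 16-lipid-per-leaflet ensemble with chains and probes."""
    spec = mp.EnsembleSpec(
        n_lipids_per_leaflet=16, n_frames=20, seed=11,
        target_scd={("sn1", 5): 0.20, ("sn2", 5): -0.20, ("sn1", 10): 0.10},
    )
    system, traj, truth = mp.generate_bilayer_ensemble(spec)
    selections = mp.resolve_selections(system)
    return spec, system, traj, truth, selections


@pytest.fixture(scope="session")
def zero_noise_ensemble():
    spec = mp.EnsembleSpec(
        n_lipids_per_leaflet=4, n_frames=1, positional_noise_sigma=0.0,
        seed=0, target_scd={},
        probe_spec=mp.ProbeSpec(n_probes=2, z_sigma=0.0, tilt_sigma=0.0,
                                hbond_type_frequencies={"NA": 1.0}),
    )
    system, traj, truth = mp.generate_bilayer_ensemble(spec)
    selections = mp.resolve_selections(system)
    return spec, system, traj, truth, selections


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
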