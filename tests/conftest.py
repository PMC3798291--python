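"""Shared fixtures: simulated study-design datasets and derived objects."""

import numpy as np
import pandas as pd
import pytest

import actikin as ak


@pytest.fixture(scope="session")
def study_config():
    """The replicated time-course design with planted induction.

    2000 single-probe-set genes, 20% induced with peak Z in [8, 15],
    6 controls + 3 replicates at each of 1/4/8/24 h.
    """
    return ak.SimConfig(
        n_genes=2000,
        frac_induced=0.2,
        effect_size_z_range=(8.0, 15.0),
        multi_probeset_frac=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def study_dataset(study_config):
    return ak.simulate_timecourse(study_config)


@pytest.fixture(scope="session")
def multi_probeset_dataset():
    """Dataset with multi-probe-set genes and planted discordance."""
    cfg = ak.SimConfig(
        n_genes=800,
        frac_induced=0.2,
        effect_size_z_range=(8.0, 15.0),
        multi_probeset_frac=0.4,
        discordant_frac=0.3,
        seed=4,
    )
    return ak.simulate_timecourse(cfg)


@pytest.fixture(scope="session")
def study_calls(study_dataset):
    ds = study_dataset
    model = ak.fit_error_model(ds.expression, ds.design)
    z = ak.compute_z(ds.expression, ds.design, model)
    return ak.call_induced(z, ds.presence, probe_map=ds.probe_map)


def make_archetype_profiles(n_per_archetype=200, noise_sd=0.05, seed=2):
    """Unit-normalised profiles around the five kinetic archetypes."""
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for arch in ak.ARCHETYPES:
        base = np.asarray(arch.profile, dtype=float)
        base = base / np.linalg.norm(base)
        for i in range(n_per_archetype):
            v = base + rng.normal(0.0, noise_sd, size=base.size)
            v = v / np.linalg.norm(v)
            rows.append(v)
            labels.append(arch.id)
            ids.append(f"a{arch.id}_p{i:03d}")
    idx = pd.Index(ids, name="probe_set_id")
    profiles = pd.DataFrame(rows, index=idx, columns=[1, 4, 8, 24])
    truth = pd.Series(labels, index=idx, name="archetype")
    return ak.ProfileMatrix(normalized=profiles, raw=profiles.copy()), truth
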