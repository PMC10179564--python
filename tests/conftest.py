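import numpy as np
import pytest

import reachkin as rk


@pytest.fixture(scope="session")
def tiny_config():
    """2 post-stroke + 1 control participant, 1 recording per limb."""
    return rk.SimulationConfig(n_stroke_participants=2, n_control_participants=1,
                               recordings_per_limb=1, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    recordings, manifest = rk.simulate_cohort(tiny_config)
    return recordings, manifest


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort):
    recordings, manifest = tiny_cohort
    sets = [rk.preprocess_recording(r)[0] for r in recordings]
    return rk.build_feature_matrix(sets, rk.core_catalog(), manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


# Worked-example grid of common significant-feature counts per kinematic
# series (one cell per series name), used to exercise the aggregation
# arithmetic: marker totals 338/459/104/103, grand total 1004.
EXAMPLE_COUNT_GRID = {
    "ACRA": 38, "ACRV": 35, "ACRD": 13,
    "ACRx": 52, "ACRy": 0, "ACRz": 0,
    "ACRax": 26, "ACRay": 14, "ACRaz": 35,
    "ACRvx": 29, "ACRvy": 9, "ACRvz": 30,
    "ACRdx": 42, "ACRdy": 11, "ACRdz": 4,
    "MPHA": 62, "MPHV": 62, "MPHD": 15,
    "MPHx": 47, "MPHy": 6, "MPHz": 14,
    "MPHax": 34, "MPHay": 12, "MPHaz": 35,
    "MPHvx": 42, "MPHvy": 7, "MPHvz": 53,
    "MPHdx": 37, "MPHdy": 30, "MPHdz": 3,
    "LEPA": 18, "LEPV": 7, "LEPD": 3,
    "LEPx": 31, "LEPy": 3, "LEPz": 11,
    "LEPax": 2, "LEPay": 3, "LEPaz": 4,
    "LEPvx": 3, "LEPvy": 0, "LEPvz": 0,
    "LEPdx": 14, "LEPdy": 3, "LEPdz": 2,
    "FNA": 7, "FNV": 0, "FND": 12,
    "FNx": 1, "FNy": 8, "FNz": 11,
    "FNax": 5, "FNay": 11, "FNaz": 29,
    "FNvx": 3, "FNvy": 0, "FNvz": 7,
    "FNdx": 0, "FNdy": 6, "FNdz": 3,
}
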