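from __future__ import annotations

import numpy as np
import pytest

import microreach as mr


@pytest.fixture(scope="session")
def default_session():
    """One full synthetic session under the default study conditions."""
    cfg = mr.SessionConfig(rng_seed=12345)
    units, trials, rf_maps = mr.simulate_session(cfg)
    return cfg, units, trials, rf_maps


@pytest.fixture(scope="session")
def default_profiles(default_session):
    """Kept trials and per-unit z-profiles of the default session."""
    _, units, trials, _ = default_session
    kept, excluded = mr.filter_trials(trials)
    spec = mr.PethSpec()
    zps = [mr.build_zprofile(u, kept, spec) for u in units]
    return spec, units, kept, excluded, zps


def make_zprofile(spec: mr.PethSpec, z: np.ndarray, baseline_mean: float = 20.0) -> mr.ZProfile:
    """A hand-built profile whose rate is consistent with the given z trace."""
    lefts = spec.bin_lefts
    z = np.asarray(z, dtype=float)
    assert z.shape == lefts.shape
    sd = 1.0
    rate = baseline_mean + sd * z
    return mr.ZProfile(
        bin_lefts=lefts,
        rate_raw=rate.copy(),
        rate=rate,
        z=z,
        baseline_mean=baseline_mean,
        baseline_sd=sd,
        n_trials=1,
    )
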