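"""Shared fixtures.

The expensive prior-campaign library is built once per session and shared by
the campaign, inference and acceptance tests.
"""

import numpy as np
import pytest

from neulink.library import run_campaign
from neulink.model import PhysConstants, PriorBox, StimulusProtocol


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol(seed=101)


@pytest.fixture(scope="session")
def constants():
    return PhysConstants()


@pytest.fixture(scope="session")
def library_small(protocol, constants):
    """2,000-simulation prior library for unit-level checks."""
    return run_campaign(2000, PriorBox(), protocol, constants, seed=2024,
                        batch_size=500)


@pytest.fixture(scope="session")
def library_large(protocol, constants):
    """20,000-simulation prior library shared by the inference benchmarks."""
    return run_campaign(20000, PriorBox(), protocol, constants, seed=77,
                        batch_size=2000)


@pytest.fixture(scope="session")
def sim_features_fn(protocol, constants, library_large):
    """θ-matrix -> z-scored transformed features (NaN rows where invalid)."""
    from neulink.features import (extract_features_batch, transform_features,
                                  valid_mask)
    from neulink.model import simulate_batch

    std = library_large.standardizer

    def fn(thetas):
        vm, _ = simulate_batch(np.atleast_2d(thetas), protocol, constants,
                               sim_indices=np.arange(len(np.atleast_2d(thetas))))
        tf = transform_features(extract_features_batch(vm, protocol))
        z = std.transform(tf)
        z[~valid_mask(tf)] = np.nan
        return z

    return fn


@pytest.fixture(scope="session")
def misspec_benchmark(library_large, protocol, constants, sim_features_fn):
    """Standard NPE vs noise-augmented NPE on 50 synthetic observations,
    with and without a systematic 0.5-SD feature-space shift.

    Returns a dict with the four posterior-predictive reports, the
    observations and the random-prior baseline distances.
    """
    from neulink.model import sample_prior
    from neulink.npe import TrainingSchedule, evaluate_fit, select_training_set, train_npe
    from neulink.synthetic import make_cells, make_observations

    lib = library_large
    theta_true, _ = make_cells(n_families=10, cells_per_family=5, spread=0.03,
                               seed=500, protocol=protocol, constants=constants)
    obs_zero = make_observations(theta_true, lib.standardizer, protocol,
                                 constants, shift=0.0, meas_sd=0.05, seed=501)
    obs_shift = obs_zero + 0.5  # same cells under a systematic mismatch

    def fit(mode, obs, sd, seed):
        sched = TrainingSchedule(mode=mode, noise_sd_features=sd, seed=seed)
        th, x = select_training_set(lib, obs, sched)
        return train_npe(th, x, lib, sched, seed=seed + 1)

    standard = fit("standard", None, 0.0, 502)
    npen_shift = fit("noise_features", obs_shift, 0.1, 502)
    npen_zero = fit("noise_features", obs_zero, 0.1, 502)

    reports = {
        ("standard", "shift"): evaluate_fit(standard, obs_shift, sim_features_fn, seed=504),
        ("npen", "shift"): evaluate_fit(npen_shift, obs_shift, sim_features_fn, seed=505),
        ("standard", "zero"): evaluate_fit(standard, obs_zero, sim_features_fn, seed=506),
        ("npen", "zero"): evaluate_fit(npen_zero, obs_zero, sim_features_fn, seed=506),
    }

    # schedule comparison at zero shift needs the training replicate as the
    # statistical unit: a single fitted network carries its own bias, so the
    # per-replicate mean of paired per-observation differences is what the
    # paired test must act on
    zero_replicates = [(np.asarray(reports[("standard", "zero")].map_distances),
                        np.asarray(reports[("npen", "zero")].map_distances))]
    for r, seed in enumerate((602, 702), start=1):
        s = fit("standard", None, 0.0, seed)
        nz = fit("noise_features", obs_zero, 0.1, seed)
        ra = evaluate_fit(s, obs_zero, sim_features_fn, seed=seed + 2)
        rb = evaluate_fit(nz, obs_zero, sim_features_fn, seed=seed + 2)
        zero_replicates.append((np.asarray(ra.map_distances),
                                np.asarray(rb.map_distances)))

    # random-prior baseline: 10 draws per observation, distances of the
    # defined simulations to their observation
    draws = sample_prior(10 * len(obs_zero), seed=508)
    f = sim_features_fn(draws)
    base = []
    for i, o in enumerate(obs_zero):
        chunk = f[10 * i:10 * (i + 1)]
        ok = np.all(np.isfinite(chunk), axis=1)
        base.extend(np.linalg.norm(chunk[ok] - o, axis=1))
    return {"reports": reports, "obs_zero": obs_zero, "obs_shift": obs_shift,
            "theta_true": theta_true, "prior_baseline": np.asarray(base),
            "zero_replicates": zero_replicates}


def make_template_trace(peaks_ms=(150.0, 250.0, 350.0), baseline=-60.0,
                        peak_vm=20.0, dip_vm=-65.0):
    """Piecewise-linear trace with identical template spikes.

    Each spike: 2 ms linear upstroke from baseline to peak (40 mV/ms, well
    above the 20 mV/ms detection criterion), 2 ms downstroke to a dip below
    baseline, 1 ms recovery.  Thresholds and peaks are therefore known
    exactly, which makes every spike-derived feature hand-computable.
    """
    from neulink.model import StimulusProtocol, VoltageTrace

    prot = StimulusProtocol(noise_enabled=False)
    t = prot.time_grid()
    v = np.full_like(t, baseline)
    for pk in peaks_ms:
        up = (t >= pk - 2.0) & (t <= pk)
        v[up] = baseline + (t[up] - (pk - 2.0)) / 2.0 * (peak_vm - baseline)
        down = (t > pk) & (t <= pk + 2.0)
        v[down] = peak_vm + (t[down] - pk) / 2.0 * (dip_vm - peak_vm)
        rec = (t > pk + 2.0) & (t <= pk + 3.0)
        v[rec] = dip_vm + (t[rec] - (pk + 2.0)) / 1.0 * (baseline - dip_vm)
    return VoltageTrace(t=t, vm=v, protocol=prot)
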