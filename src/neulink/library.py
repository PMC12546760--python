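"""Prior simulation campaigns and the resulting feature library.

A campaign draws parameter sets from the prior box, simulates each under the
standard current-step protocol, extracts and transforms the 23 features, and
records which simulations are *valid* (all features defined).  The library
carries the feature standardizer fitted on its own valid rows — every
z-scored quantity downstream refers back to this standardizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .features import (
    FeatureStandardizer,
    extract_features_batch,
    transform_features,
    valid_mask,
)
from .model import (
    PhysConstants,
    PriorBox,
    StimulusProtocol,
    sample_prior,
    simulate_batch,
)

__all__ = ["SimulationLibrary", "run_campaign", "valid_fraction", "best_prior_match"]


@dataclass
class SimulationLibrary:
    """Parameter matrix, feature matrices, validity mask and standardizer."""

    params: np.ndarray        # (n, 13)
    raw: np.ndarray           # (n, 23) raw features, NaN = undefined
    transformed: np.ndarray   # (n, 23) log/sigmoid-transformed features
    valid: np.ndarray         # (n,) bool
    standardizer: FeatureStandardizer
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return self.params.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def z_features(self, rows=None) -> np.ndarray:
        """Standardized transformed features (NaN rows stay NaN)."""
        if self.standardizer is None:
            raise ValueError("library has no standardizer (no valid rows)")
        X = self.transformed if rows is None else self.transformed[rows]
        return self.standardizer.transform(X)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("params", data=self.params, chunks=True)
            f.create_dataset("raw", data=self.raw, chunks=True)
            f.create_dataset("transformed", data=self.transformed, chunks=True)
            f.create_dataset("valid", data=self.valid)
            f.attrs["standardizer"] = json.dumps(
                self.standardizer.to_dict() if self.standardizer else None)
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def load(cls, path) -> "SimulationLibrary":
        with h5py.File(path, "r") as f:
            return cls(
                params=f["params"][:],
                raw=f["raw"][:],
                transformed=f["transformed"][:],
                valid=f["valid"][:].astype(bool),
                standardizer=(FeatureStandardizer.from_dict(sd)
                              if (sd := json.loads(f.attrs["standardizer"]))
                              is not None else None),
                provenance=json.loads(f.attrs["provenance"]),
            )


def run_campaign(n: int, box: PriorBox | None = None,
                 protocol: StimulusProtocol | None = None,
                 constants: PhysConstants | None = None,
                 seed: int = 0, batch_size: int = 1000,
                 checkpoint: str | Path | None = None,
                 progress: bool = False) -> SimulationLibrary:
    """Simulate ``n`` prior draws and assemble a :class:`SimulationLibrary`.

    Parameters are drawn once from ``seed``; the per-simulation noise streams
    are keyed by (protocol.seed, simulation index), so the result is
    independent of ``batch_size``.  If ``checkpoint`` is given, partial
    feature matrices are flushed there after every batch and an interrupted
    campaign resumes from the last completed batch.
    """
    if n < 100:
        raise ValueError("a campaign needs at least 100 simulations")
    box = box or PriorBox()
    protocol = protocol or StimulusProtocol()
    constants = constants or PhysConstants()

    theta = sample_prior(n, box, seed)
    raw = np.full((n, 23), np.nan)
    start = 0

    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt is not None and ckpt.exists():
        with h5py.File(ckpt, "r") as f:
            if f.attrs.get("seed") == seed and f.attrs.get("n") == n:
                start = int(f.attrs["n_done"])
                raw[:start] = f["raw"][:start]

    for lo in range(start, n, batch_size):
        hi = min(lo + batch_size, n)
        vm, _ = simulate_batch(theta[lo:hi], protocol, constants,
                               sim_indices=np.arange(lo, hi))
        raw[lo:hi] = extract_features_batch(vm, protocol)
        if ckpt is not None:
            _flush_checkpoint(ckpt, seed, n, hi, raw)
        if progress:
            print(f"campaign: {hi}/{n} simulations", flush=True)

    transformed = transform_features(raw)
    valid = valid_mask(transformed)
    # a campaign with (almost) no valid rows still yields a library — e.g.
    # a passive-only prior box — it just cannot standardize features
    standardizer = (FeatureStandardizer().fit(transformed, valid)
                    if valid.sum() >= 2 else None)
    prov = {
        "seed": seed,
        "n": n,
        "dt": protocol.dt,
        "protocol": {"t_total": protocol.t_total, "t_on": protocol.t_on,
                     "t_off": protocol.t_off, "noise": protocol.noise_enabled,
                     "noise_seed": protocol.seed},
        "constants": vars(constants).copy() if hasattr(constants, "__dict__")
                     else {k: getattr(constants, k) for k in
                           ("E_Na", "E_K", "E_Ca", "Q10", "T_experiment",
                            "T_ref_kinetics", "I_inj", "noise_mean", "noise_sd")},
    }
    lib = SimulationLibrary(params=theta, raw=raw, transformed=transformed,
                            valid=valid, standardizer=standardizer,
                            provenance=prov)
    if ckpt is not None and ckpt.exists():
        ckpt.unlink()  # campaign completed; checkpoint no longer needed
    return lib


def _flush_checkpoint(path: Path, seed, n, n_done, raw):
    with h5py.File(path, "a") as f:
        if "raw" not in f:
            f.create_dataset("raw", shape=raw.shape, dtype=float)
            f.attrs["seed"] = seed
            f.attrs["n"] = n
        f["raw"][:n_done] = raw[:n_done]
        f.attrs["n_done"] = n_done


def valid_fraction(lib: SimulationLibrary) -> float:
    """Fraction of simulations with all 23 features defined."""
    return float(np.mean(lib.valid))


def best_prior_match(observation_z: np.ndarray, lib: SimulationLibrary):
    """Valid library row with the smallest Euclidean distance in z-space.

    ``observation_z`` must be standardized with the library's standardizer.
    Returns ``(params, distance, row_index)``; ties break to the lowest row.
    """
    observation_z = np.asarray(observation_z, float)
    if not np.all(np.isfinite(observation_z)):
        raise ValueError("observation has undefined features")
    rows = np.flatnonzero(lib.valid)
    if len(rows) == 0:
        raise ValueError("library has no valid simulations")
    Z = lib.z_features(rows)
    d = np.linalg.norm(Z - observation_z, axis=1)
    i = int(np.argmin(d))  # argmin returns the first minimum: lowest row wins
    return lib.params[rows[i]], float(d[i]), int(rows[i])
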