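"""File formats: traces (CSV/HDF5), feature tables (CSV + JSON sidecar),
posterior-model checkpoints (single .npz archive)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureStandardizer
from .mdn import MixtureDensityNetwork
from .model import PARAM_NAMES, PriorBox, StimulusProtocol, VoltageTrace
from .npe import PosteriorEstimator, _ParamStandardizer

__all__ = [
    "write_trace_csv", "read_trace_csv", "write_trace_h5", "read_trace_h5",
    "write_feature_table", "read_feature_table",
    "write_params_csv", "read_params_csv",
    "save_posterior", "load_posterior",
]


def write_trace_csv(trace: VoltageTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.t, "vm_mV": trace.vm}).to_csv(path, index=False)


def read_trace_csv(path, protocol: StimulusProtocol | None = None) -> VoltageTrace:
    df = pd.read_csv(path)
    for col in ("time_ms", "vm_mV"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing required column '{col}'")
    t = df["time_ms"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    if protocol is None:
        protocol = StimulusProtocol(t_total=float(t[-1]), dt=dt, noise_enabled=False)
    return VoltageTrace(t=t, vm=df["vm_mV"].to_numpy(float), protocol=protocol)


def write_trace_h5(trace: VoltageTrace, path) -> None:
    prot = trace.protocol
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.t)
        f.create_dataset("vm", data=trace.vm)
        f.attrs.update({"dt": prot.dt, "t_on": prot.t_on, "t_off": prot.t_off,
                        "t_total": prot.t_total, "seed": prot.seed,
                        "noise_enabled": prot.noise_enabled})
        if trace.params is not None:
            for name, val in zip(PARAM_NAMES, trace.params):
                f.attrs[f"param_{name}"] = val


def read_trace_h5(path) -> VoltageTrace:
    with h5py.File(path, "r") as f:
        prot = StimulusProtocol(
            t_total=float(f.attrs["t_total"]), t_on=float(f.attrs["t_on"]),
            t_off=float(f.attrs["t_off"]), dt=float(f.attrs["dt"]),
            noise_enabled=bool(f.attrs["noise_enabled"]), seed=int(f.attrs["seed"]))
        params = None
        if f"param_{PARAM_NAMES[0]}" in f.attrs:
            params = np.array([f.attrs[f"param_{n}"] for n in PARAM_NAMES])
        return VoltageTrace(t=f["time"][:], vm=f["vm"][:], protocol=prot,
                            params=params)


def write_feature_table(features: np.ndarray, path, transformed: bool = False,
                        standardizer: FeatureStandardizer | None = None,
                        ids=None) -> None:
    """Feature matrix to CSV (empty cells = undefined) plus a JSON sidecar
    recording the transform state and, optionally, the standardizer."""
    features = np.atleast_2d(features)
    df = pd.DataFrame(features, columns=list(FEATURE_NAMES))
    if ids is not None:
        df.insert(0, "cell_id", ids)
    df.to_csv(path, index=False)
    sidecar = {"transformed": bool(transformed),
               "standardizer": standardizer.to_dict() if standardizer else None}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path):
    """Returns (matrix, ids-or-None, sidecar dict)."""
    df = pd.read_csv(path)
    ids = df.pop("cell_id").to_numpy() if "cell_id" in df.columns else None
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s): {missing}")
    mat = df[list(FEATURE_NAMES)].to_numpy(float)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return mat, ids, sidecar


def write_params_csv(theta: np.ndarray, path, ids=None) -> None:
    df = pd.DataFrame(np.atleast_2d(theta), columns=list(PARAM_NAMES))
    if ids is not None:
        df.insert(0, "cell_id", ids)
    df.to_csv(path, index=False)


def read_params_csv(path):
    df = pd.read_csv(path)
    ids = df.pop("cell_id").to_numpy() if "cell_id" in df.columns else None
    missing = [c for c in PARAM_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table is missing column(s): {missing}")
    return df[list(PARAM_NAMES)].to_numpy(float), ids


def read_expression(path, genes_path=None):
    """Cells × genes counts from CSV (cell id index, gene columns) or MTX.

    For MTX, gene and cell names come from ``<path>.genes.txt`` and
    ``<path>.cells.txt`` (one name per line) when present.  Returns
    ``(counts, gene_names, cell_ids)``; if ``genes_path`` names a gene panel
    (one symbol per line), the matrix is restricted to that panel.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(path)
        counts = np.asarray(m.toarray() if hasattr(m, "toarray") else m, dtype=float)
        genes_file = Path(str(path) + ".genes.txt")
        cells_file = Path(str(path) + ".cells.txt")
        gene_names = (genes_file.read_text().split()
                      if genes_file.exists()
                      else [f"gene_{i}" for i in range(counts.shape[1])])
        cell_ids = (cells_file.read_text().split()
                    if cells_file.exists()
                    else [f"cell_{i}" for i in range(counts.shape[0])])
    else:
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy(float)
        gene_names = list(df.columns)
        cell_ids = list(df.index)
    if len(gene_names) != counts.shape[1]:
        raise ValueError("gene-name count does not match matrix columns")
    if genes_path is not None:
        panel = set(Path(genes_path).read_text().split())
        keep = [i for i, g in enumerate(gene_names) if g in panel]
        if not keep:
            raise ValueError("no panel genes found in the expression matrix")
        counts = counts[:, keep]
        gene_names = [gene_names[i] for i in keep]
    return counts, gene_names, cell_ids


def save_posterior(posterior: PosteriorEstimator, path) -> None:
    """Single-file checkpoint: network weights + standardizers + prior box."""
    mdn = posterior.mdn
    meta = {
        "mdn_params": mdn.get_params(),
        "dx": mdn.dx_, "dy": mdn.dy_,
        "param_standardizer": posterior.param_standardizer.to_dict(),
        "feature_standardizer": posterior.feature_standardizer.to_dict(),
        "prior_low": posterior.prior_box.low.tolist(),
        "prior_high": posterior.prior_box.high.tolist(),
        "metadata": posterior.metadata,
    }
    arrays = {f"w{i}": w for i, w in enumerate(mdn.weights_)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_posterior(path) -> PosteriorEstimator:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"w{i}"] for i in range(10)]
    params = meta["mdn_params"]
    params["hidden"] = tuple(params["hidden"])
    mdn = MixtureDensityNetwork(**params)
    mdn.weights_ = weights
    mdn.dx_, mdn.dy_ = meta["dx"], meta["dy"]
    return PosteriorEstimator(
        mdn,
        _ParamStandardizer.from_dict(meta["param_standardizer"]),
        FeatureStandardizer.from_dict(meta["feature_standardizer"]),
        PriorBox(np.array(meta["prior_low"]), np.array(meta["prior_high"])),
        metadata=meta["metadata"],
    )
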