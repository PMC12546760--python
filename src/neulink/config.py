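"""Run configuration: YAML round-trip and provenance digest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import PhysConstants, PriorBox, StimulusProtocol

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on.

    ``model`` overrides prior-box bounds and physical constants; the
    remaining blocks control the campaign, the training schedule, the
    gene-linkage model and the synthetic cohort.
    """

    seed: int = 0
    campaign_n: int = 20000
    batch_size: int = 2000
    prior_overrides: dict = field(default_factory=dict)   # name -> [low, high]
    constants: dict = field(default_factory=dict)          # PhysConstants fields
    protocol: dict = field(default_factory=dict)           # StimulusProtocol fields
    schedule: dict = field(default_factory=lambda: {
        "mode": "noise_features", "noise_sd_features": 0.1, "K": 1000})
    srrr: dict = field(default_factory=lambda: {
        "rank": 2, "alpha": 0.5, "lam_grid": [0.05, 0.1, 0.2, 0.5, 1.0],
        "folds": 5})
    cohort: dict = field(default_factory=lambda: {
        "n_families": 6, "cells_per_family": 25, "spread": 0.03,
        "shift": 0.0, "meas_sd": 0.05, "n_genes": 400, "n_informative": 20,
        "loading_scale": 1.0})
    n_posterior_samples: int = 10
    map_n_samples: int = 10000

    # -- construction helpers ----------------------------------------------

    def prior_box(self) -> PriorBox:
        box = PriorBox()
        if self.prior_overrides:
            box = box.replace(**{k: tuple(v) for k, v in self.prior_overrides.items()})
        return box

    def phys_constants(self) -> PhysConstants:
        return PhysConstants(**self.constants)

    def stimulus_protocol(self) -> StimulusProtocol:
        kw = dict(self.protocol)
        kw.setdefault("seed", self.seed)
        return StimulusProtocol(**kw)

    # -- round-trip ---------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the full configuration, logged with every run."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
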