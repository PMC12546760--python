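"""Synthetic cohorts: ground-truth cells, observations, and transcriptomes.

Every inference stage of the package can be exercised without any external
recordings by generating (i) parameter sets organized into cell families,
(ii) observation feature vectors derived by simulating those parameters —
optionally with a constant z-space shift that mimics the systematic
model-data mismatch seen with real recordings — and (iii) overdispersed
count matrices in which a small set of informative genes carries a sparse
linear map from the biophysical parameters.

Defaults mirror the shape of a cortical Patch-seq study at desk scale:
6 families of ~150 cells, a 400-gene panel with 20 informative genes,
negative-binomial dispersion 0.5 and lognormal depth variation (CV 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (
    FeatureStandardizer,
    extract_features_batch,
    transform_features,
    valid_mask,
)
from .model import PhysConstants, PriorBox, StimulusProtocol, simulate_batch

__all__ = ["SyntheticCohort", "make_cells", "make_observations", "make_expression"]


@dataclass
class SyntheticCohort:
    theta: np.ndarray             # (cells, 13) true parameters
    labels: np.ndarray            # (cells,) family labels
    observations_z: np.ndarray    # (cells, 23) z-space observed features
    shift: np.ndarray             # (23,) applied mismatch shift, z units
    counts: np.ndarray            # (cells, genes)
    loadings: np.ndarray          # (genes, 13) informative-gene map
    gene_names: list


def make_cells(n_families: int = 6, cells_per_family: int = 150,
               spread: float = 0.03, seed: int = 0,
               box: PriorBox | None = None,
               protocol: StimulusProtocol | None = None,
               constants: PhysConstants | None = None,
               max_tries: int = 200):
    """Family-structured ground-truth parameters, all feature-valid.

    Family centers are drawn uniformly in the central 60% of the prior box
    and re-drawn until the center itself simulates to a valid feature
    vector; members jitter around the center with SD ``spread`` × range,
    truncated to the box, and are re-sampled until their own simulations are
    valid.  Returns ``(theta, labels)``.
    """
    box = box or PriorBox()
    protocol = protocol or StimulusProtocol()
    constants = constants or PhysConstants()
    rng = np.random.default_rng(seed)
    rngspan = box.high - box.low
    lo60 = box.low + 0.2 * rngspan
    hi60 = box.high - 0.2 * rngspan

    def batch_valid(theta):
        vm, _ = simulate_batch(theta, protocol, constants,
                               sim_indices=rng.integers(0, 2 ** 31, len(theta)))
        return valid_mask(transform_features(extract_features_batch(vm, protocol)))

    theta_all, labels = [], []
    for fam in range(n_families):
        center = None
        for _ in range(max_tries):
            cand = lo60 + rng.random((8, 13)) * (hi60 - lo60)
            ok = batch_valid(cand)
            if ok.any():
                center = cand[np.argmax(ok)]
                break
        if center is None:
            raise RuntimeError("could not find a valid family center")
        members = []
        for _ in range(max_tries):
            need = cells_per_family - len(members)
            if need <= 0:
                break
            cand = center + rng.normal(0.0, spread, (max(need * 2, 8), 13)) * rngspan
            cand = np.clip(cand, box.low, box.high)
            if spread == 0:
                cand[:] = center
            ok = batch_valid(cand)
            members.extend(cand[ok][:need])
            if spread == 0 and ok.any():
                members = [center] * cells_per_family
                break
        if len(members) < cells_per_family:
            raise RuntimeError(f"family {fam}: only {len(members)} valid cells")
        theta_all.append(np.asarray(members))
        labels.extend([fam] * cells_per_family)
    return np.vstack(theta_all), np.asarray(labels)


def make_observations(theta: np.ndarray, standardizer: FeatureStandardizer,
                      protocol: StimulusProtocol | None = None,
                      constants: PhysConstants | None = None,
                      shift: np.ndarray | float = 0.0, meas_sd: float = 0.0,
                      seed: int = 0, max_retries: int = 30) -> np.ndarray:
    """Simulate each parameter set into a z-scored observation vector.

    Each row is featurized, transformed, standardized with the supplied
    (library) standardizer, then offset by the constant ``shift`` (scalar or
    per-feature, z units — the systematic model-data mismatch) plus
    independent N(0, meas_sd²) measurement noise.  Rows whose simulation
    happens to produce an undefined feature are re-simulated with fresh
    noise streams.
    """
    protocol = protocol or StimulusProtocol()
    constants = constants or PhysConstants()
    theta = np.atleast_2d(np.asarray(theta, float))
    n = len(theta)
    shift = np.broadcast_to(np.asarray(shift, float), (23,)).copy()
    rng = np.random.default_rng(seed)

    feats = np.full((n, 23), np.nan)
    pending = np.arange(n)
    for attempt in range(max_retries):
        if len(pending) == 0:
            break
        vm, _ = simulate_batch(theta[pending], protocol, constants,
                               sim_indices=pending + attempt * n + seed % (2 ** 20))
        tf = transform_features(extract_features_batch(vm, protocol))
        ok = valid_mask(tf)
        feats[pending[ok]] = tf[ok]
        pending = pending[~ok]
    if len(pending):
        raise RuntimeError(f"{len(pending)} cells never produced valid features")
    z = standardizer.transform(feats)
    return z + shift + rng.normal(0.0, meas_sd, z.shape)


def make_expression(theta: np.ndarray, labels: np.ndarray, n_genes: int = 400,
                    n_informative: int = 20, loading_scale: float = 1.0,
                    dispersion: float = 0.5, depth_cv: float = 0.3,
                    base_depth: float = 2e4, marker_strength: float = 1.0,
                    seed: int = 0):
    """Overdispersed counts whose informative genes encode the parameters.

    Informative genes' log-rates are ``baseline + loading · z(θ)`` where
    each loading row touches a few parameters and is scaled so the signal
    SD in log-rate space equals ``loading_scale``.  One marker gene per
    family receives a label-specific offset.  Counts are negative-binomial
    with the given dispersion; per-cell depth is lognormal with CV
    ``depth_cv``.  Returns ``(counts, loadings, gene_names)``.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, float)
    n = len(theta)
    z = (theta - theta.mean(axis=0)) / np.where(theta.std(axis=0) == 0, 1.0,
                                                theta.std(axis=0))

    loadings = np.zeros((n_genes, 13))
    info = rng.choice(n_genes, n_informative, replace=False)
    for g in info:
        k = rng.integers(1, 4)
        idx = rng.choice(13, k, replace=False)
        w = rng.standard_normal(k)
        loadings[g, idx] = w
    # scale each informative row so sd(loading . z) ~= loading_scale
    sig = loadings[info] @ z.T
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    loadings[info] = loadings[info] / sd * loading_scale

    baseline = rng.uniform(0.5, 3.0, n_genes)  # log mean expression
    lograte = baseline[None, :] + z @ loadings.T

    families = np.unique(labels)
    markers = rng.choice(np.setdiff1d(np.arange(n_genes), info),
                         len(families), replace=False)
    for fam, g in zip(families, markers):
        lograte[np.asarray(labels) == fam, g] += marker_strength

    depth_sigma = np.sqrt(np.log(1 + depth_cv ** 2))
    depth = rng.lognormal(-depth_sigma ** 2 / 2, depth_sigma, n)
    rate = np.exp(lograte)
    rate = rate / rate.sum(axis=1, keepdims=True) * base_depth * depth[:, None]

    r = 1.0 / dispersion  # NB: var = mu + dispersion * mu^2
    p = r / (r + rate)
    counts = rng.negative_binomial(r, p)
    gene_names = [f"gene_{i:04d}" for i in range(n_genes)]
    return counts.astype(np.int64), loadings, gene_names
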