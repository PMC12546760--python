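"""Neural posterior estimation over the biophysical parameters.

The posterior q(θ|x) over the 13 parameters given the 23 summary features is
learned from a prior simulation library by conditional density estimation
(:class:`~neulink.mdn.MixtureDensityNetwork`), with both θ and x z-scored.

Training schedules address model misspecification — the systematic offset
between the simulator's feature manifold and real recordings:

``standard``
    all valid (θ, x) pairs of the library.
``best_euclidean``
    only the K nearest valid simulations (z-space Euclidean) per observation.
``noise_features`` (NPE-N)
    the near-observation subset with isotropic Gaussian noise of a given SD
    (in z units) added to the features — smoothing the feature manifold so
    the estimator generalizes across the model-data gap.
``noise_features_params``
    additionally perturbs the parameters.
``data_augmentation``
    clean near-observation pairs concatenated with their noised copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .features import feature_distance
from .library import SimulationLibrary
from .mdn import MixtureDensityNetwork
from .model import PriorBox

__all__ = [
    "TrainingSchedule",
    "FitReport",
    "PosteriorEstimator",
    "select_training_set",
    "train_npe",
    "posterior_entropy",
    "normalize_entropies",
    "evaluate_fit",
]

SCHEDULE_MODES = ("standard", "best_euclidean", "noise_features",
                  "noise_features_params", "data_augmentation")


def child_seed(master: int, salt: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([master, salt]).generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class TrainingSchedule:
    mode: str = "standard"
    noise_sd_features: float = 0.0   # z units
    noise_sd_params: float = 0.0     # z units
    K: int | None = None             # nearest simulations per observation;
                                     # None -> min(10000, n_valid // 10)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in SCHEDULE_MODES:
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.noise_sd_features < 0 or self.noise_sd_params < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.K is not None and self.mode != "standard" and self.K < 1:
            raise ValueError("K must be at least 1")


@dataclass
class FitReport:
    """Posterior-predictive evaluation: failure rates and feature distances.

    ``map_distances`` holds the per-observation MAP distance (NaN where the
    MAP simulation failed), enabling paired comparisons between schedules.
    """

    map_fail_pct: float
    map_dist_mean: float
    map_dist_sd: float
    posterior_fail_pct: float
    posterior_dist_mean: float
    posterior_dist_sd: float
    n_observations: int
    map_distances: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if d["map_distances"] is not None:
            d["map_distances"] = np.asarray(d["map_distances"]).tolist()
        return d


def select_training_set(lib: SimulationLibrary, observations_z: np.ndarray | None,
                        schedule: TrainingSchedule):
    """Assemble (θ_z-scored-ready raw θ, x_z) training pairs per the schedule.

    Returns raw parameters and *z-scored* features; feature/parameter noise
    is applied in z units.  Subset modes take the union (deduplicated) of the
    K nearest valid simulations to each observation.
    """
    valid_rows = np.flatnonzero(lib.valid)
    Z = lib.z_features(valid_rows)

    if schedule.mode == "standard":
        sel = np.arange(len(valid_rows))
    else:
        if observations_z is None:
            raise ValueError(f"schedule {schedule.mode!r} needs observations")
        obs = np.atleast_2d(observations_z)
        K = schedule.K
        if K is None:
            K = min(10_000, max(1, len(valid_rows) // 10))
        if len(valid_rows) < K:
            raise ValueError("fewer valid simulations than neighborhood size K")
        chosen = set()
        for o in obs:
            d = np.linalg.norm(Z - o, axis=1)
            near = np.argpartition(d, K - 1)[:K]
            chosen.update(near.tolist())
        sel = np.fromiter(sorted(chosen), dtype=int)

    theta = lib.params[valid_rows[sel]].copy()
    x = Z[sel].copy()

    rng = np.random.default_rng(schedule.seed)
    if schedule.mode in ("noise_features", "noise_features_params"):
        x = x + rng.normal(0.0, schedule.noise_sd_features, x.shape)
        if schedule.mode == "noise_features_params" and schedule.noise_sd_params > 0:
            theta_sd = lib.params[lib.valid].std(axis=0)
            theta = theta + rng.normal(0.0, schedule.noise_sd_params,
                                       theta.shape) * theta_sd
    elif schedule.mode == "data_augmentation":
        x_noisy = x + rng.normal(0.0, schedule.noise_sd_features, x.shape)
        theta = np.vstack([theta, theta])
        x = np.vstack([x, x_noisy])
    return theta, x


class _ParamStandardizer:
    def __init__(self, theta):
        self.mean_ = theta.mean(axis=0)
        self.scale_ = theta.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0

    def transform(self, theta):
        return (np.asarray(theta, float) - self.mean_) / self.scale_

    def inverse_transform(self, z):
        return np.asarray(z, float) * self.scale_ + self.mean_

    def to_dict(self):
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d):
        obj = cls.__new__(cls)
        obj.mean_ = np.asarray(d["mean"], float)
        obj.scale_ = np.asarray(d["scale"], float)
        return obj


class PosteriorEstimator:
    """Trained conditional posterior over raw parameters given z features.

    Wraps the density network together with the parameter standardizer, the
    library's feature standardizer and the prior box; all public methods work
    in raw parameter units and z-scored feature units.
    """

    def __init__(self, mdn: MixtureDensityNetwork, param_standardizer,
                 feature_standardizer, prior_box: PriorBox, metadata=None):
        self.mdn = mdn
        self.param_standardizer = param_standardizer
        self.feature_standardizer = feature_standardizer
        self.prior_box = prior_box
        self.metadata = metadata or {}

    # densities are over z-scored θ; the Jacobian is constant so comparisons
    # (MAP, entropy differences) are unaffected
    def log_prob(self, theta, x_z):
        tz = self.param_standardizer.transform(np.atleast_2d(theta))
        return self.mdn.log_prob(tz, x_z)

    def sample(self, x_z, n: int, seed: int = 0, max_rounds: int = 1000):
        """n posterior draws inside the prior box (rejection against the box)."""
        x_z = np.asarray(x_z, float)
        if not np.all(np.isfinite(x_z)):
            raise ValueError("observation has undefined features")
        rng = np.random.default_rng(seed)
        out = []
        got = tried = 0
        for _ in range(max_rounds):
            draw = self.mdn.sample(x_z, max(n, 256), rng)
            theta = self.param_standardizer.inverse_transform(draw)
            ok = self.prior_box.contains(theta)
            tried += len(theta)
            if ok.any():
                out.append(theta[ok])
                got += int(ok.sum())
            if got >= n:
                break
            if tried >= 256_000 and got < 0.001 * tried:
                frac_out = np.mean((theta < self.prior_box.low)
                                   | (theta > self.prior_box.high), axis=0)
                worst = int(np.argmax(frac_out))
                raise RuntimeError(
                    "posterior mass leaks out of the prior box "
                    f"(acceptance < 0.1%; worst dimension index {worst})")
        return np.vstack(out)[:n]

    def map_estimate(self, x_z, n_samples: int = 10_000, seed: int = 0,
                     refine: bool = True) -> np.ndarray:
        """Highest-density of ``n_samples`` posterior draws, then local ascent.

        The gradient ascent runs on z-scored θ inside the (z-scored) prior
        box; refinement can only increase the posterior density.
        """
        samples = self.sample(x_z, n_samples, seed=seed)
        lp = self.log_prob(samples, x_z)
        best = samples[int(np.argmax(lp))]
        if not refine:
            return best
        ps = self.param_standardizer
        z0 = ps.transform(best[None, :])[0]
        lo = ps.transform(self.prior_box.low[None, :])[0]
        hi = ps.transform(self.prior_box.high[None, :])[0]
        x_z = np.asarray(x_z, float)

        def neg(z):
            return -float(self.mdn.log_prob(z[None, :], x_z)[0])

        def grad(z):
            return -self.mdn.grad_log_prob_y(z, x_z)

        res = minimize(neg, z0, jac=grad, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)))
        if np.isfinite(res.fun) and -res.fun >= float(np.max(lp)):
            return ps.inverse_transform(res.x[None, :])[0]
        return best


def train_npe(theta: np.ndarray, x_z: np.ndarray, lib: SimulationLibrary,
              schedule: TrainingSchedule | None = None, seed: int = 0,
              mdn_kwargs: dict | None = None) -> PosteriorEstimator:
    """Fit the conditional density estimator on (θ, x) pairs.

    θ is given raw and z-scored internally against the library's valid
    parameter distribution; x must already be z-scored features.
    """
    kwargs = dict(n_components=8, hidden=(50, 50), seed=child_seed(seed, 1))
    if mdn_kwargs:
        kwargs.update(mdn_kwargs)
    ps = _ParamStandardizer(lib.params[lib.valid])
    mdn = MixtureDensityNetwork(**kwargs)
    mdn.fit(x_z, ps.transform(theta))
    meta = {"schedule": vars(schedule).copy() if schedule else None,
            "n_pairs": int(len(theta)), "seed": seed}
    return PosteriorEstimator(mdn, ps, lib.standardizer, PriorBox(),
                              metadata=meta)


def posterior_entropy(posterior: PosteriorEstimator, x_z, n: int = 1000,
                      seed: int = 0) -> float:
    """Monte-Carlo uncertainty score: -sum of log q over n posterior draws."""
    samples = posterior.sample(x_z, n, seed=seed)
    return float(-np.sum(posterior.log_prob(samples, x_z)))


def normalize_entropies(values) -> np.ndarray:
    """Scale a collection of per-cell entropies by the least-entropy cell."""
    values = np.asarray(values, float)
    return values / values.min()


def evaluate_fit(posterior: PosteriorEstimator, observations_z: np.ndarray,
                 simulate_features_fn, n_posterior_samples: int = 10,
                 seed: int = 0, map_n_samples: int = 10_000) -> FitReport:
    """Posterior-predictive check in the style of a fail-rate/distance table.

    For every observation, simulate the MAP parameters and
    ``n_posterior_samples`` posterior draws; a simulation *fails* if any
    transformed feature is undefined, otherwise its z-space Euclidean
    distance to the observation is recorded.  Failed simulations count only
    toward the fail percentage, not the distance statistics.

    ``simulate_features_fn(theta_matrix)`` must return z-scored transformed
    features (rows of NaN where undefined).
    """
    obs = np.atleast_2d(observations_z)
    n_obs = obs.shape[0]

    d = len(posterior.prior_box.low)
    maps = np.empty((n_obs, d))
    post = np.empty((n_obs, n_posterior_samples, d))
    for i, o in enumerate(obs):
        s_map = child_seed(seed, 2 * i)
        s_post = child_seed(seed, 2 * i + 1)
        try:
            maps[i] = posterior.map_estimate(o, n_samples=map_n_samples,
                                             seed=s_map)
            post[i] = posterior.sample(o, n_posterior_samples, seed=s_post)
        except RuntimeError:
            # posterior mass entirely outside the prior box: the fit cannot
            # propose parameters at all, which the protocol counts as failed
            maps[i] = np.nan
            post[i] = np.nan

    f_map = simulate_features_fn(maps)
    f_post = simulate_features_fn(post.reshape(-1, d)).reshape(
        n_obs, n_posterior_samples, -1)

    def stats(feats, targets):
        ok = np.all(np.isfinite(feats), axis=-1)
        dists = [feature_distance(f, t)
                 for f, t, k in zip(feats.reshape(-1, feats.shape[-1]),
                                    targets, ok.ravel()) if k]
        fail_pct = 100.0 * (1.0 - ok.mean())
        if dists:
            return fail_pct, float(np.mean(dists)), float(np.std(dists))
        return fail_pct, float("nan"), float("nan")

    map_fail, map_mu, map_sd = stats(f_map, obs)
    tiled = np.repeat(obs, n_posterior_samples, axis=0)
    post_fail, post_mu, post_sd = stats(f_post, tiled)
    ok = np.all(np.isfinite(f_map), axis=1)
    per_obs = np.full(n_obs, np.nan)
    per_obs[ok] = np.linalg.norm(f_map[ok] - obs[ok], axis=1)
    return FitReport(map_fail, map_mu, map_sd, post_fail, post_mu, post_sd,
                     n_obs, map_distances=per_obs)
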