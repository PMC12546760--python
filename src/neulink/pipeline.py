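"""End-to-end orchestration: campaign → train → infer → evaluate → gene link.

Each stage writes one artifact into the run directory and is skipped on
rerun if its artifact already exists, so a run resumes at the first missing
stage.  All randomness derives from the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .features import transform_features, valid_mask
from .io import (
    load_posterior,
    save_posterior,
    write_feature_table,
    write_params_csv,
)
from .library import SimulationLibrary, run_campaign
from .model import simulate_batch
from .npe import (
    TrainingSchedule,
    child_seed,
    evaluate_fit,
    normalize_entropies,
    posterior_entropy,
    select_training_set,
    train_npe,
)
from .srrr import (
    SparseRRR,
    classify_from_params,
    cross_validate_srrr,
    per_target_r2,
    preprocess_expression,
    select_lambda,
)
from .synthetic import make_cells, make_expression, make_observations

log = logging.getLogger("neulink")

ARTIFACTS = ("library.h5", "cohort.npz", "model.npz", "posterior.npz",
             "map_params.csv", "entropy.csv", "evaluation.json",
             "srrr_report.json")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run (or resume) the full pipeline; returns paths of the artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline run, config digest %s", config.digest())
    (outdir / "config.yaml").write_text(config.to_yaml())

    box = config.prior_box()
    constants = config.phys_constants()
    protocol = config.stimulus_protocol()
    paths = {name: outdir / name for name in ARTIFACTS}

    # 1. prior campaign
    if paths["library.h5"].exists():
        lib = SimulationLibrary.load(paths["library.h5"])
        log.info("campaign: reusing %s", paths["library.h5"])
    else:
        log.info("campaign: %d simulations", config.campaign_n)
        lib = run_campaign(config.campaign_n, box, protocol, constants,
                           seed=child_seed(config.seed, 10),
                           batch_size=config.batch_size,
                           checkpoint=outdir / "library.partial.h5")
        lib.save(paths["library.h5"])

    # 2. synthetic cohort (ground truth cells + observations + expression)
    if paths["cohort.npz"].exists():
        with np.load(paths["cohort.npz"], allow_pickle=False) as d:
            theta, labels = d["theta"], d["labels"]
            obs_z, counts = d["obs_z"], d["counts"]
        log.info("cohort: reusing %s", paths["cohort.npz"])
    else:
        c = config.cohort
        theta, labels = make_cells(
            c["n_families"], c["cells_per_family"], c["spread"],
            seed=child_seed(config.seed, 20), box=box, protocol=protocol,
            constants=constants)
        obs_z = make_observations(
            theta, lib.standardizer, protocol, constants, shift=c["shift"],
            meas_sd=c["meas_sd"], seed=child_seed(config.seed, 21))
        counts, loadings, _ = make_expression(
            theta, labels, c["n_genes"], c["n_informative"],
            c["loading_scale"], seed=child_seed(config.seed, 22))
        np.savez(paths["cohort.npz"], theta=theta, labels=labels,
                 obs_z=obs_z, counts=counts, loadings=loadings)
        write_feature_table(obs_z, outdir / "observations.csv", transformed=True,
                            standardizer=lib.standardizer)

    # 3. train the posterior
    if paths["model.npz"].exists():
        posterior = load_posterior(paths["model.npz"])
        log.info("train: reusing %s", paths["model.npz"])
    else:
        schedule = TrainingSchedule(seed=child_seed(config.seed, 30),
                                    **config.schedule)
        pairs_theta, pairs_x = select_training_set(lib, obs_z, schedule)
        log.info("train: %d pairs, schedule %s", len(pairs_theta), schedule.mode)
        posterior = train_npe(pairs_theta, pairs_x, lib, schedule,
                              seed=child_seed(config.seed, 31))
        save_posterior(posterior, paths["model.npz"])

    # 4. posterior samples, MAP table, entropy table
    if not (paths["posterior.npz"].exists() and paths["map_params.csv"].exists()
            and paths["entropy.csv"].exists()):
        maps = np.empty((len(obs_z), 13))
        ent = np.empty(len(obs_z))
        samples = np.empty((len(obs_z), config.n_posterior_samples, 13))
        for i, o in enumerate(obs_z):
            s = child_seed(config.seed, 40 + i)
            maps[i] = posterior.map_estimate(o, config.map_n_samples, seed=s)
            samples[i] = posterior.sample(o, config.n_posterior_samples, seed=s)
            ent[i] = posterior_entropy(posterior, o, seed=s)
        np.savez(paths["posterior.npz"], samples=samples)
        write_params_csv(maps, paths["map_params.csv"])
        rel = normalize_entropies(ent)
        np.savetxt(paths["entropy.csv"],
                   np.column_stack([ent, rel]), delimiter=",",
                   header="entropy,relative_entropy", comments="")
    else:
        from .io import read_params_csv
        maps, _ = read_params_csv(paths["map_params.csv"])

    # 5. posterior-predictive evaluation
    if not paths["evaluation.json"].exists():
        def sim_features(thetas):
            vm, _ = simulate_batch(thetas, protocol, constants,
                                   sim_indices=np.arange(len(thetas)))
            from .features import extract_features_batch
            tf = transform_features(extract_features_batch(vm, protocol))
            z = lib.standardizer.transform(tf)
            z[~valid_mask(tf)] = np.nan
            return z

        report = evaluate_fit(posterior, obs_z, sim_features,
                              config.n_posterior_samples,
                              seed=child_seed(config.seed, 50))
        paths["evaluation.json"].write_text(json.dumps(report.to_dict(), indent=1))

    # 6. gene linkage
    if not paths["srrr_report.json"].exists():
        X = preprocess_expression(counts)
        Ymu, Ysd = maps.mean(0), maps.std(0)
        Yz = (maps - Ymu) / np.where(Ysd == 0, 1, Ysd)
        cfg = config.srrr
        cv = cross_validate_srrr(X, Yz, cfg["lam_grid"], cfg["alpha"],
                                 cfg["rank"], cfg["folds"],
                                 seed=child_seed(config.seed, 60))
        lam = select_lambda(cv)
        model = SparseRRR(rank=cfg["rank"], lam=lam, alpha=cfg["alpha"]).fit(X, Yz)
        pred = model.predict(X)
        report = {
            "lambda": lam,
            "cv": {k: np.asarray(v).tolist() for k, v in cv.items()},
            "n_selected_genes": model.n_selected_,
            "selected_genes": model.selected_genes_.tolist(),
            "per_target_r2": per_target_r2(Yz, pred).tolist(),
            "pooled_r2": model.score(X, Yz),
            "family_accuracy": classify_from_params(
                maps, labels, seed=child_seed(config.seed, 61)),
            "group_distance_family": None,
        }
        from .srrr import group_average_distance
        report["group_distance_family"] = group_average_distance(maps, pred * Ysd + Ymu, labels)
        paths["srrr_report.json"].write_text(json.dumps(report, indent=1))

    return {k: str(v) for k, v in paths.items()}
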