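"""Top-level pipeline driver.

Runs diversity -> covariate PCA -> trajectory mixed model -> both
RI-CLPM temperament variants -> per-role feature associations, writing
every stage's output plus a run manifest (package version, seed, config
hash) so a rerun with the same config and seed reproduces the outputs
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import reduce_covariates
from .diversity import diversity_table
from .feature_assoc import FeatureAssociation
from .io import PipelineConfig, read_tables
from .riclpm import DyadicRICLPM, RiclpmSpec, build_panel
from .trajectory import fit_trajectory

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _write_posterior(model: DyadicRICLPM, path: Path) -> None:
    summary = model.summary_.reset_index()
    payload = {
        "summary": summary.to_dict(orient="records"),
        "significant_paths": model.significant_paths_,
        "max_rhat": model.max_rhat_,
    }
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of in-memory results.

    Stage failures abort with the stage name; outputs written before the
    failure are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {}
    stage = "read"
    try:
        tables = read_tables(
            {k: getattr(config, k) for k in ("counts", "metadata", "behavior", "covariates")}
        )

        stage = "diversity"
        div = diversity_table(tables["counts"], config.metric, metadata=tables["metadata"])
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = div

        stage = "covariates"
        pcs = reduce_covariates(tables["covariates"], config.n_components)
        pcs.scores.to_csv(out / "pcs.tsv", sep="\t")
        pcs.loadings.to_csv(out / "pc_loadings.tsv", sep="\t")
        results["pcs"] = pcs

        stage = "trajectory"
        traj_data = div.join(pcs.scores, on="dyad_id")
        traj = fit_trajectory(traj_data)
        posthoc = traj.posthoc_pairwise()
        fit_json = {
            "coefficients": {
                name: {"B": traj.params_[name], "SE": traj.bse_[name],
                       "t": traj.tvalues_[name], "p": traj.pvalues_[name]}
                for name in traj.params_.index
            },
            "sigma2": traj.sigma2_, "tau2": traj.tau2_,
            "reml_loglik": traj.reml_loglik_,
            "n_obs": traj.n_obs_, "n_subjects": traj.n_subjects_,
            "posthoc": [dataclasses.asdict(c) for c in posthoc],
        }
        (out / "trajectory.json").write_text(json.dumps(fit_json, indent=2, default=float))
        results["trajectory"] = traj
        results["posthoc"] = posthoc

        stage = "riclpm"
        spec = RiclpmSpec(seed=config.seed, **config.riclpm)
        for variant in config.temperament_variants:
            panel = build_panel(
                div[["sample_id", "value", "subject_id", "dyad_id", "role", "wave"]],
                tables["behavior"], tables["metadata"], pcs.scores, temperament=variant,
            )
            model = DyadicRICLPM(spec).fit(panel)
            _write_posterior(model, out / f"posterior_{variant.lower()}.json")
            results[f"riclpm_{variant}"] = model

        stage = "feature_assoc"
        for role in ("infant", "mother"):
            assoc = FeatureAssociation(
                role=role,
                min_abundance=config.min_abundance,
                min_prevalence=config.min_prevalence,
                q_threshold=config.q_threshold,
            ).fit(
                tables["counts"], metadata=tables["metadata"],
                behavior=tables["behavior"], pcs=pcs.scores,
            )
            assoc.results_.to_csv(out / f"associations_{role}.tsv", sep="\t", index=False)
            results[f"assoc_{role}"] = assoc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package": "microdyad",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    # elapsed time is diagnostic; the manifest identity excludes it
    identity = {k: v for k, v in manifest.items() if k != "elapsed_s"}
    manifest["identity_hash"] = __import__("hashlib").sha256(
        json.dumps(identity, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
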