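"""End-to-end orchestration: simulate/load -> summarize -> ordinate ->
disparity -> phylogenetic signal -> convergence -> classifiers -> fossil
predictions, with serialized outputs and a reproducibility manifest.

Stages communicate only through their serialized interfaces (CSV/JSON under
the output directory), so any stage can be rerun or replaced in isolation.
Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf_mod
from . import convergence as conv_mod
from . import disparity as disp_mod
from . import io_core, morphometrics, ordination, phylo_signal, synthetic

log = logging.getLogger("melanomorph.pipeline")

STAGES = (
    "simulate",
    "summarize",
    "ordinate",
    "disparity",
    "signal",
    "convergence",
    "train",
    "predict",
)


@dataclass
class PipelineConfig:
    seed: int
    measurements_path: str | None = None
    tree_path: str | None = None
    fossil_path: str | None = None
    simulation: dict = field(default_factory=dict)
    alphas: tuple = disp_mod.DEFAULT_ALPHAS
    n_randomization: int = 5000
    n_bootstrap: int = 1000
    n_permutations: int = 999
    cv_folds: int = 10
    cv_repeats: int = 5
    shrinkage_fractions: tuple = (0.10, 0.20, 0.30)
    exclude_species: tuple = ()
    min_n: int = 10
    outdir: str = "melanomorph_out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_randomization", "n_bootstrap", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "seed" not in raw:
            raise ValueError("pipeline config must be a mapping with a 'seed'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("alphas", "shrinkage_fractions", "exclude_species"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _timed(manifest: dict, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                manifest["failed_stage"] = stage
                log.error("stage %s: FAILED after %.2fs", stage, dt)
                return False
            manifest["stages"][stage]["seconds"] = round(dt, 3)
            log.info("stage %s: done in %.2fs", stage, dt)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {s: {"outputs": []} for s in STAGES},
    }

    def emit(stage: str, name: str):
        path = out / name
        manifest["stages"][stage]["outputs"].append(name)
        return path

    try:
        # -- simulate / load ---------------------------------------------
        with _timed(manifest, "simulate"):
            if config.measurements_path:
                table = io_core.read_measurements(config.measurements_path)
                tree = io_core.read_tree(config.tree_path)
                traits = None
            else:
                sim = synthetic.SimulationConfig(
                    seed=config.seed, **config.simulation
                )
                tree, traits, table = synthetic.make_dataset(sim)
                traits.to_csv(emit("simulate", "species_traits.csv"), index=False)
            table, report = io_core.filter_dataset(
                table, config.exclude_species, config.min_n
            )
            io_core.write_measurements(table, emit("simulate", "measurements.csv"))
            io_core.write_tree(tree, emit("simulate", "tree.nwk"))
            io_core.write_filter_report(
                report, emit("simulate", "filter_report.json")
            )
            if config.fossil_path:
                fossil_table = io_core.read_measurements(config.fossil_path)
            else:
                # synthetic fossils: shrunk unlabeled copies of a few samples
                rng = np.random.default_rng(config.seed + 900)
                ids = pd.unique(table["sample_id"])
                chosen = rng.choice(ids, size=min(6, len(ids)), replace=False)
                fossil_table = synthetic.apply_shrinkage(
                    table[table["sample_id"].isin(chosen)].copy(), 0.15
                )
                fossil_table["sample_id"] = "fossil_" + fossil_table["sample_id"]
            io_core.write_measurements(
                fossil_table, emit("simulate", "fossil_measurements.csv")
            )

        # -- summarize -----------------------------------------------------
        with _timed(manifest, "summarize"):
            summaries = morphometrics.summarize_table(table)
            summaries.to_csv(emit("summarize", "sample_summaries.csv"), index=False)
            fossil_summaries = morphometrics.summarize_table(fossil_table)
            fossil_summaries.to_csv(
                emit("summarize", "fossil_summaries.csv"), index=False
            )

        # -- ordinate ------------------------------------------------------
        with _timed(manifest, "ordinate"):
            ordn = ordination.fit_pcamix(summaries)
            ordn.to_json(emit("ordinate", "ordination.json"))
            ordn.scores.to_csv(emit("ordinate", "scores.csv"))
            fossil_scores = ordn.project(
                fossil_summaries, index=fossil_summaries["sample_id"]
            )
            fossil_scores.to_csv(emit("ordinate", "fossil_scores.csv"))
            per_species = morphometrics.species_means(summaries)
            species_scores = ordn.project(
                per_species, index=per_species["species"]
            )
            species_scores.index.name = "species"
            species_scores.to_csv(emit("ordinate", "species_scores.csv"))

        # -- disparity -----------------------------------------------------
        with _timed(manifest, "disparity"):
            labels = summaries["color_category"].to_numpy()
            S3 = ordn.scores.to_numpy()[:, :3]
            vols = disp_mod.category_volumes(S3, labels, config.alphas)
            vols.to_csv(emit("disparity", "category_volumes.csv"), index=False)
            rand = disp_mod.randomization_test(
                S3, labels, n_iter=config.n_randomization, seed=config.seed + 1
            )
            sov = disp_mod.sum_of_variances(
                ordn.scores.to_numpy(), labels,
                n_boot=config.n_bootstrap, seed=config.seed + 2,
            )
            sov.to_csv(emit("disparity", "sum_of_variances.csv"), index=False)
            with open(emit("disparity", "disparity.json"), "w") as fh:
                json.dump(
                    dict(
                        observed_ratio=rand.observed_ratio,
                        p_value=rand.p_value,
                        exact_binomial_p=rand.exact_binomial_p,
                        n_iter=rand.n_iter,
                        n_degenerate=rand.n_degenerate,
                    ),
                    fh, indent=2,
                )

        # -- phylogenetic signal -------------------------------------------
        with _timed(manifest, "signal"):
            sp_scores = species_scores
            km = phylo_signal.kmult(
                sp_scores, tree, n_perm=config.n_permutations,
                seed=config.seed + 3,
            )
            per_axis = {}
            for col in sp_scores.columns:
                k1 = phylo_signal.kmult(
                    sp_scores[[col]], tree, n_perm=config.n_permutations,
                    seed=config.seed + 4,
                )
                lam = phylo_signal.pagels_lambda(sp_scores[col], tree)
                per_axis[col] = {"K": k1.value, "K_p": k1.p_value,
                                 "lambda": lam.value, "lambda_p": lam.p_value}
            anc = phylo_signal.ancestral_states(sp_scores, tree)
            edges = phylo_signal.phylomorphospace_edges(sp_scores, anc, tree)
            edges.to_csv(emit("signal", "phylomorphospace_edges.csv"), index=False)
            with open(emit("signal", "signal.json"), "w") as fh:
                json.dump(
                    dict(
                        K_mult=km.value, K_mult_p=km.p_value,
                        n_permutations=km.n_permutations, per_axis=per_axis,
                    ),
                    fh, indent=2,
                )

        # -- convergence ---------------------------------------------------
        with _timed(manifest, "convergence"):
            if traits is not None:
                report = conv_mod.convergence_report(
                    summaries, tree, traits,
                    pcamix_scores=sp_scores,
                    n_boot=config.n_bootstrap, seed=config.seed + 5,
                )
            else:
                report = pd.DataFrame(
                    [dict(note="no origin metadata; convergence skipped")]
                )
            report.to_csv(emit("convergence", "convergence.csv"), index=False)

        # -- train ---------------------------------------------------------
        with _timed(manifest, "train"):
            perf_rows = []
            models = {}
            for kind, variables in (
                ("mlr", clf_mod.DEFAULT_MLR_VARIABLES),
                ("qda", clf_mod.DEFAULT_QDA_VARIABLES),
            ):
                model = clf_mod.fit(summaries, kind, variables)
                model.to_json(emit("train", f"model_{kind}.json"))
                cv = clf_mod.cross_validate(
                    summaries, kind, variables, k=config.cv_folds,
                    repeats=config.cv_repeats, seed=config.seed + 6,
                )
                decay, _ = clf_mod.model_decay(
                    model, summaries, config.shrinkage_fractions
                )
                models[kind] = model
                perf_rows.append(
                    dict(model=kind, accuracy_pct=100 * cv.accuracy,
                         decay_pct=decay, exact_p=cv.exact_p, kappa=cv.kappa)
                )
            perf = pd.DataFrame.from_records(perf_rows)
            perf.to_csv(emit("train", "model_performance.csv"), index=False)

        # -- predict ---------------------------------------------------------
        with _timed(manifest, "predict"):
            preds = clf_mod.predict_fossil(models["mlr"], fossil_summaries)
            preds.to_csv(emit("predict", "fossil_predictions.csv"), index=False)

    finally:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
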