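"""End-to-end orchestration: simulate -> featurize -> train -> evaluate ->
abc -> interpret, driven by a single YAML run configuration.

Every stage writes its artifacts under the run's output directory and
records completion in ``manifest.json``; a rerun resumes from the last
completed stage.  All randomness derives from the master seed, so an
identical configuration reproduces identical feature tables and tree-model
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import abc as abc_mod
from . import io as io_mod
from .demography import PriorSpec, SampleDesign, default_priors
from .evaluation import error_surface, evaluate_predictions
from .inference import RegressorConfig, train_regressor
from .interpret import class_importance, permutation_importance, shapley_values
from .simulate import build_reference_table
from .sumstats import StatConfig, build_schema

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "train", "evaluate", "abc", "interpret")


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    model: str = "IM"
    seed: int = 0
    output_dir: str = "run"
    n_sims: int = 40
    split: tuple[int, int, int] = (24, 8, 8)
    design: SampleDesign = field(default_factory=SampleDesign)
    priors: dict[str, PriorSpec] | None = None  # None: model defaults
    stats: StatConfig = field(default_factory=StatConfig)
    methods: tuple[str, ...] = ("RF", "XGB", "MLP")
    regressor_overrides: dict = field(default_factory=dict)
    abc_algorithms: tuple[str, ...] = ("rejection", "loclinear", "neuralnet")
    abc_tolerance: float = 0.05
    abc_point: str = "mean"
    abc_max_stats: int = 300
    abc_n_targets: int = 8
    interpret_method: str = "XGB"
    interpret_target: str = "split_time"
    n_background: int = 100
    n_explain: int = 20
    n_jobs: int = 1

    def resolved_priors(self) -> dict[str, PriorSpec]:
        return self.priors if self.priors is not None else default_priors(self.model)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        d["stats"] = dataclasses.asdict(self.stats)
        d["split"] = list(self.split)
        d["methods"] = list(self.methods)
        d["abc_algorithms"] = list(self.abc_algorithms)
        if self.priors is not None:
            d["priors"] = {k: [v.low, v.high] for k, v in self.priors.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = SampleDesign(**d["design"])
        if "stats" in d:
            d["stats"] = StatConfig(**d["stats"])
        if d.get("priors") is not None:
            d["priors"] = {k: PriorSpec(k, *v) for k, v in d["priors"].items()}
        for key in ("split", "methods", "abc_algorithms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Record of a run: config snapshot, seeds, schema hash, checkpoints."""

    config: dict
    schema_hash: str
    stage_seeds: dict
    completed: dict = field(default_factory=dict)  # stage -> unix time
    versions: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _schema_hash(names) -> str:
    import hashlib

    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(STAGES.index(stage) + 1,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, log=print, until: str | None = None) -> RunManifest:
    """Execute all stages, resuming from the last completed checkpoint.

    With ``until`` set to a stage name, later stages are not run (they stay
    resumable on the next invocation).
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = STAGES.index(until) if until is not None else len(STAGES) - 1

    def wanted(stage: str) -> bool:
        return STAGES.index(stage) <= last

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    priors = config.resolved_priors()
    schema = build_schema(config.design, config.stats)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.schema_hash != _schema_hash(schema.names):
            raise RuntimeError("existing run directory has a different schema")
    else:
        import sklearn
        import msprime as _msp
        import xgboost as _xgb

        manifest = RunManifest(
            config=config.to_dict(),
            schema_hash=_schema_hash(schema.names),
            stage_seeds={s: _stage_seed(config.seed, s) for s in STAGES},
            versions={
                "numpy": np.__version__,
                "sklearn": sklearn.__version__,
                "msprime": _msp.__version__,
                "xgboost": _xgb.__version__,
            },
        )
    io_mod.write_schema_manifest(schema, out / "schema.json")

    def done(stage):
        manifest.completed[stage] = time.time()
        manifest.save(manifest_path)
        log(f"[{stage}] complete")

    # ---- simulate + featurize -------------------------------------------
    if wanted("simulate") and "simulate" not in manifest.completed:
        log(f"[simulate] {config.n_sims} simulations of {config.design.n_loci} loci")
        table = build_reference_table(
            config.model, priors, config.design, config.n_sims,
            tuple(config.split), manifest.stage_seeds["simulate"],
            stat_config=config.stats, n_jobs=config.n_jobs,
            checkpoint_path=out / "features.checkpoint.npz",
        )
        io_mod.write_reference_table(table, out)
        (out / "features.checkpoint.npz").unlink(missing_ok=True)
        done("simulate")
    table = io_mod.read_reference_table(out, schema)

    X_train, P_train = table.subset("train")
    X_val, P_val = table.subset("validation")
    X_test, P_test = table.subset("test")
    param_names = table.param_names

    # ---- train ----------------------------------------------------------
    models_path = out / "models.joblib"
    if wanted("train") and ("train" not in manifest.completed or not models_path.exists()):
        models = {}
        for method in config.methods:
            for k, param in enumerate(param_names):
                cfg = RegressorConfig(
                    method=method, seed=manifest.stage_seeds["train"],
                    **config.regressor_overrides,
                )
                log(f"[train] {method} for {param}")
                models[(param, method)] = train_regressor(
                    cfg, X_train, P_train[:, k], X_val, P_val[:, k],
                    target=param, prior=priors[param],
                    feature_names=table.feature_names,
                )
        joblib.dump(models, models_path)
        done("train")
    if not wanted("train"):
        return manifest
    models = joblib.load(models_path)

    # ---- evaluate -------------------------------------------------------
    if wanted("evaluate") and "evaluate" not in manifest.completed:
        predictions = {key: m.predict(X_test) for key, m in models.items()}
        targets = {p: P_test[:, k] for k, p in enumerate(param_names)}
        report = evaluate_predictions(targets, predictions, priors)
        report.metrics.to_csv(out / "metrics.csv")
        from .plots import plot_error_surface, plot_predicted_vs_observed

        plot_predicted_vs_observed(report, out / "predicted_vs_observed.png")
        if X_test.shape[0] >= 50:
            for k, param in enumerate(param_names):
                best = min(
                    (m for (p, m) in models if p == param),
                    key=lambda m: report.metrics.loc[(param, m), "MAE"],
                )
                errs = (predictions[(param, best)] - P_test[:, k]) / priors[param].width
                surf = error_surface(
                    errs, P_test, param_names, seed=manifest.stage_seeds["evaluate"]
                )
                plot_error_surface(surf, out / f"error_surface_{param}.png",
                                   title=f"{param} ({best})")
        done("evaluate")

    # ---- abc ------------------------------------------------------------
    if wanted("abc") and "abc" not in manifest.completed:
        import pandas as pd

        ref_idx = np.concatenate([table.rows("train"), table.rows("validation")])
        ref_stats, ref_params = table.features[ref_idx], table.params[ref_idx]
        rows = []
        n_targets = min(config.abc_n_targets, X_test.shape[0])
        algos = {
            "rejection": lambda s, p: abc_mod.abc_rejection(s, ref_stats, p, config.abc_tolerance),
            "loclinear": lambda s, p: abc_mod.abc_loclinear(
                s, ref_stats, p, config.abc_tolerance, config.abc_max_stats),
            "neuralnet": lambda s, p: abc_mod.abc_neuralnet(
                s, ref_stats, p, config.abc_tolerance, config.abc_max_stats,
                seed=manifest.stage_seeds["abc"]),
        }
        for t in range(n_targets):
            for k, param in enumerate(param_names):
                for algo in config.abc_algorithms:
                    res = algos[algo](X_test[t], ref_params[:, k])
                    rows.append({
                        "target": t, "parameter": param, "algorithm": algo,
                        "estimate": abc_mod.point_estimate(res, config.abc_point),
                        "truth": P_test[t, k], "n_accepted": res.n_accepted,
                    })
        pd.DataFrame(rows).to_csv(out / "abc_results.csv", index=False)
        done("abc")

    # ---- interpret ------------------------------------------------------
    if wanted("interpret") and "interpret" not in manifest.completed:
        import pandas as pd

        key = (config.interpret_target, config.interpret_method)
        model = models[key]
        k = param_names.index(config.interpret_target)
        seed = manifest.stage_seeds["interpret"]
        pfi = permutation_importance(
            model, X_test, P_test[:, k], seed=seed, feature_names=table.feature_names
        )
        pfi.top(50).to_csv(out / "importance_top.csv", index=False)
        cls_imp = class_importance(pfi, schema)
        pd.Series(cls_imp).to_csv(out / "class_importance.csv", header=["fraction"])
        rng = np.random.default_rng(seed)
        bg = X_train[rng.choice(X_train.shape[0], min(config.n_background, X_train.shape[0]),
                                replace=False)]
        explain = X_test[: config.n_explain]
        shap_report = shapley_values(model, bg, explain, seed=seed)
        shap_report.mean_abs().head(50).to_csv(out / "shap_mean_abs.csv", header=["mean_abs_shap"])
        from .plots import plot_shap_beeswarm, plot_shap_dependence

        plot_shap_beeswarm(shap_report, out / "shap_beeswarm.png")
        plot_shap_dependence(
            shap_report, shap_report.mean_abs().index[0], out / "shap_dependence.png"
        )
        done("interpret")

    return manifest
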