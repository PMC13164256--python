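"""End-to-end orchestration: dataset -> preprocessing -> surrogates -> CV ->
importance -> structure sweeps -> release table, from a single config.

The report bundle mirrors the tables a study of this kind prints: dataset
summary statistics, model metrics, per-fold CV scores, feature importance,
per-electrolyte diameter statistics, and the release-kinetics table, plus a
run log with every seed and library version for reproducibility.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset_io, importance, regressors, release_kinetics, synthetic_data
from .dataset_io import MODEL_FIELDS

__all__ = ["PipelineConfig", "ReportBundle", "run", "write_bundle"]


@dataclass
class PipelineConfig:
    generator: synthetic_data.GeneratorConfig | None = field(
        default_factory=synthetic_data.GeneratorConfig)
    dataset_path: str | None = None
    required_fields: tuple = MODEL_FIELDS
    encoding_mode: str = "onehot"
    test_fraction: float = 0.22
    split_seed: int = 42
    network: regressors.NetworkConfig = field(
        default_factory=regressors.NetworkConfig)
    cv_k: int = 5
    cv_seed: int = 7
    release_params: release_kinetics.ReleaseParams = field(
        default_factory=release_kinetics.ReleaseParams)
    release_diameters: tuple = (30.0, 50.0, 75.0, 100.0, 150.0)
    release_k_values: tuple | None = None  # explicit K list overrides the mode
    release_mode: str = "empirical"

    def __post_init__(self):
        if (self.generator is None) == (self.dataset_path is None):
            raise ValueError(
                "exactly one of generator / dataset_path must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "generator" in raw:
            g = raw["generator"]
            if g is None:
                kwargs["generator"] = None
            else:
                for key in ("voltage_range",):
                    if key in g:
                        g[key] = {k: tuple(v) for k, v in g[key].items()}
                for key in ("temperature_range", "time_range"):
                    if key in g:
                        g[key] = tuple(g[key])
                kwargs["generator"] = synthetic_data.GeneratorConfig(**g)
        if raw.get("dataset_path"):
            kwargs["dataset_path"] = raw["dataset_path"]
            kwargs.setdefault("generator", None)
        if "network" in raw:
            n = dict(raw["network"])
            if "hidden_sizes" in n:
                n["hidden_sizes"] = tuple(n["hidden_sizes"])
            kwargs["network"] = regressors.NetworkConfig(**n)
        if "release_params" in raw:
            kwargs["release_params"] = release_kinetics.ReleaseParams(
                **raw["release_params"])
        for key in ("required_fields", "encoding_mode", "test_fraction",
                    "split_seed", "cv_k", "cv_seed", "release_diameters",
                    "release_k_values", "release_mode"):
            if key in raw:
                value = raw[key]
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class ReportBundle:
    summary: pd.DataFrame  # dataset summary statistics
    metrics: pd.DataFrame  # model comparison (train/test + CV mean/SD)
    cv: pd.DataFrame  # per-fold CV scores
    importances: pd.DataFrame  # feature importance, both models
    electrolyte_stats: pd.DataFrame  # per-electrolyte diameter statistics
    release: pd.DataFrame  # release kinetics table
    run_log: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"summary": self.summary, "metrics": self.metrics,
                "cv": self.cv, "importance": self.importances,
                "electrolyte_stats": self.electrolyte_stats,
                "release": self.release}


def _electrolyte_stats(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for level, group in df.groupby("electrolyte", sort=True):
        d = group["pore_diameter_nm"].to_numpy(dtype=float)
        rows.append({"electrolyte": level, "count": len(d),
                     "mean_nm": d.mean(), "sd_nm": float(np.std(d)),
                     "min_nm": d.min(), "max_nm": d.max()})
    return pd.DataFrame(rows)


def _versions() -> dict:
    import sklearn
    from . import __version__
    return {"anodpore": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__}


def run(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; rerun with the same config reproduces the bundle."""
    stage = "load"
    try:
        if config.generator is not None:
            ds = synthetic_data.generate(config.generator)
            ds = synthetic_data.inject_missingness(ds)
            df = ds.frame
        else:
            df = dataset_io.read_dataset(config.dataset_path)
            df = dataset_io.canonicalize_dataset(df)

        stage = "summarize"
        summary = dataset_io.summarize(df)

        stage = "preprocess"
        complete = dataset_io.complete_cases(df, config.required_fields)
        train_df, test_df = dataset_io.stratified_split(
            complete, config.test_fraction, config.split_seed)
        train_fm, test_fm = dataset_io.encode(
            train_df, test_df, mode=config.encoding_mode)

        stage = "fit"
        mlr = regressors.fit_mlr(train_fm)
        ann = regressors.fit_ann(train_fm, config.network)
        rows = []
        for label, model in (("mlr", mlr), ("ann", ann)):
            tr = regressors.evaluate(train_fm.y,
                                     regressors.predict(model, train_fm))
            te = regressors.evaluate(test_fm.y,
                                     regressors.predict(model, test_fm))
            rows.append({"model": label, "r2_train": tr.r2, "rmse_train": tr.rmse,
                         "mae_train": tr.mae, "r2_test": te.r2,
                         "rmse_test": te.rmse, "mae_test": te.mae,
                         "n_train": tr.n, "n_test": te.n})
        metrics = pd.DataFrame(rows)

        stage = "cross-validate"
        cv_rows = []
        for spec, label in (("mlr", "mlr"), (config.network, "ann")):
            report = regressors.kfold_cv(spec, train_fm, k=config.cv_k,
                                         seed=config.cv_seed)
            for i, score in enumerate(report.fold_scores, start=1):
                cv_rows.append({"model": label, "fold": i, "r2": score})
            cv_rows.append({"model": label, "fold": "mean", "r2": report.mean})
            cv_rows.append({"model": label, "fold": "sd", "r2": report.sd})
            metrics.loc[metrics["model"] == label, "cv_r2_mean"] = report.mean
            metrics.loc[metrics["model"] == label, "cv_r2_sd"] = report.sd
        cv = pd.DataFrame(cv_rows)

        stage = "importance"
        imp_frames = []
        for report in (importance.mlr_importance(mlr),
                       importance.ann_importance(ann)):
            frame = report.to_frame()
            frame.insert(0, "method", report.method)
            imp_frames.append(frame)
        importances = pd.concat(imp_frames, ignore_index=True)

        stage = "structure"
        electrolyte_stats = _electrolyte_stats(complete)

        stage = "release"
        if config.release_k_values is not None:
            configs = list(zip(config.release_diameters,
                               config.release_k_values))
        else:
            configs = [
                (d, release_kinetics.higuchi_constant(
                    config.release_params, d, config.release_mode))
                for d in config.release_diameters]
        release = release_kinetics.release_table(configs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_log = {
        "versions": _versions(),
        "seeds": {
            "generator": (config.generator.seed
                          if config.generator is not None else None),
            "split": config.split_seed,
            "network": config.network.seed,
            "cv": config.cv_seed,
        },
        "encoding_mode": config.encoding_mode,
        "n_records": len(df),
        "n_complete": len(complete),
        "n_train": len(train_df),
        "n_test": len(test_df),
        "release_mode": (None if config.release_k_values is not None
                         else config.release_mode),
    }
    return ReportBundle(summary=summary, metrics=metrics, cv=cv,
                        importances=importances,
                        electrolyte_stats=electrolyte_stats,
                        release=release, run_log=run_log)


def write_bundle(bundle: ReportBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables().items():
        table.to_csv(out / f"{name}.csv",
                     index=(name == "summary"))
    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle.run_log, fh, indent=2)
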