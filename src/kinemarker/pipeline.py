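"""Experiment orchestration: configuration, canned recipes, deterministic runs.

The recipes chain the library stages the way the study's analyses do:
``simulate`` writes a synthetic cohort to disk (BVH recordings + manifest +
labels + ground truth), ``extract`` turns recordings into the cohort feature
table, ``cross_sectional`` / ``longitudinal`` / ``fxn`` run the nested-LOSO
GP predictions, ``learning_curve`` the cohort-size analysis and
``validate_features`` the test–retest / group-difference screens.  Every
stage derives its randomness from the single root seed and records a manifest
(config hash, package version, seeds), so identical config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .modeling import GPModelSpec, learning_curve, nested_loso_evaluate
from .synthetic import (LabelModel, NoiseModel, SyntheticCohortSpec,
                        simulate_cohort, write_bvh)
from .task_features import (CohortTable, build_feature_table,
                            group_difference_screen, test_retest_correlation)

__all__ = ["RunConfig", "run_experiment", "RECIPES"]

log = logging.getLogger("kinemarker")

RECIPES = ("simulate", "extract", "cross_sectional", "longitudinal", "fxn",
           "learning_curve", "validate_features")


@dataclass
class RunConfig:
    """All run parameters with the study's constants as defaults.

    Defaults mirror the published analysis constants: 2 cm voxels, 50
    autocorrelation bins over two cycles, 10 delay lags per cycle, 200 ms STFT
    windows with 100 ms overlap, 10 Hz low-pass, 10 s FWHM lag span.  The
    config round-trips losslessly through YAML.
    """

    data_dir: str = "data"
    out_dir: str = "results"
    experiment: str = "default"
    seed: int = 0
    # feature parameters
    voxel_edge_cm: float = 2.0
    acf_bins: int = 50
    f4_n_lags: int = 10
    stft_window_s: float = 0.2
    stft_overlap_s: float = 0.1
    lowpass_hz: float = 10.0
    fwhm_lag_s: float = 10.0
    # model
    kernel: str = "rbf"
    max_subset_size: int = 4
    horizon_months: float = 9.0
    targets: tuple[str, ...] = ("SARA", "SCAFI")
    feature_sets: tuple[str, ...] = ("8MW", "9HPT")
    learning_curve_k: tuple[int, ...] = ()
    learning_curve_max_combinations: int = 1000
    # cohort
    n_patients: int = 9
    n_controls: int = 9
    visits_months: tuple[float, ...] = (0.0, 0.75, 3.0, 9.0)
    n_repeats: int = 2
    n_peg_cycles: int = 9
    frame_rate: float = 60.0
    joint_aliases: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("targets", "feature_sets", "visits_months", "learning_curve_k"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def cohort_spec(self) -> SyntheticCohortSpec:
        return SyntheticCohortSpec(
            n_patients=self.n_patients, n_controls=self.n_controls,
            visits_months=tuple(self.visits_months), n_repeats=self.n_repeats,
            n_peg_cycles=self.n_peg_cycles, frame_rate=self.frame_rate,
            seed=self.seed)

    def model_spec(self) -> GPModelSpec:
        return GPModelSpec(kernel=self.kernel, seed=self.seed)


def _write_manifest(out: Path, config: RunConfig, recipe: str, extra=None):
    manifest = {"recipe": recipe, "experiment": config.experiment,
                "config_hash": config.config_hash(), "seed": config.seed,
                "kinemarker_version": __version__}
    if extra:
        manifest.update(extra)
    with open(out / f"{recipe}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(path: Path, producer: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing prerequisite artifact {path}; run the {producer!r} recipe first")


def _dump_json(obj, path: Path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run_experiment(config: RunConfig, recipe: str) -> dict:
    """Run one canned recipe; returns a small dict of the key outputs."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("recipe=%s experiment=%s seed=%d", recipe, config.experiment, config.seed)

    if recipe == "simulate":
        data_dir.mkdir(parents=True, exist_ok=True)
        cohort = simulate_cohort(config.cohort_spec())
        rows = []
        for (sid, vid, task, rep), rec in cohort.recordings.items():
            fname = f"{sid}_{vid}_{task}_r{rep}.bvh"
            write_bvh(rec, data_dir / fname)
            rows.append(dict(path=str(data_dir / fname), subject_id=sid, visit_id=vid,
                             task=task, repeat=rep, group=rec.group,
                             hand_dominance=rec.hand_dominance))
        manifest = pd.DataFrame(rows).sort_values(["subject_id", "visit_id", "task",
                                                   "repeat"])
        manifest.to_csv(data_dir / "manifest.csv", index=False)
        cohort.labels.to_csv(data_dir / "labels.csv", index=False, float_format="%.6f")
        truth = {
            "noiseless_labels": cohort.noiseless_labels.to_dict(orient="list"),
            "recordings": {
                "|".join(map(str, k)): {
                    "severity": t.severity,
                    "stride_boundaries": None if t.stride_boundaries is None
                    else [int(v) for v in t.stride_boundaries],
                    "mean_cycle_s": t.mean_cycle_s,
                    "place_events": None if t.place_events is None
                    else [int(v) for v in t.place_events],
                } for k, t in cohort.truth.items()},
        }
        _dump_json(truth, data_dir / "ground_truth.json")
        _write_manifest(data_dir, config, recipe,
                        {"n_recordings": len(cohort.recordings)})
        return {"n_recordings": len(cohort.recordings), "data_dir": str(data_dir)}

    if recipe == "extract":
        _require(data_dir / "manifest.csv", "simulate")
        _require(data_dir / "labels.csv", "simulate")
        manifest = pd.read_csv(data_dir / "manifest.csv")
        labels = pd.read_csv(data_dir / "labels.csv")
        table = build_feature_table(manifest, labels)
        table.df.to_csv(out_dir / "features.csv", index=False, float_format="%.10g")
        _write_manifest(out_dir, config, recipe, {"n_rows": len(table.df)})
        return {"n_rows": len(table.df), "features": str(out_dir / "features.csv")}

    # prediction recipes need the feature table
    _require(out_dir / "features.csv", "extract")
    table = CohortTable(df=pd.read_csv(out_dir / "features.csv"))
    spec = config.model_spec()

    if recipe in ("cross_sectional", "longitudinal", "fxn"):
        targets = ("FXN",) if recipe == "fxn" else tuple(config.targets)
        mode = "longitudinal" if recipe == "longitudinal" else "cross_sectional"
        if mode == "longitudinal":
            months = sorted(table.df.loc[table.df["group"] == "patient", "months"]
                            .dropna().unique())
            if not months or config.horizon_months > months[-1] + 1e-9 or len(months) < 2:
                raise ValueError(
                    f"longitudinal horizon {config.horizon_months} months needs a "
                    "multi-visit cohort reaching that horizon; rerun 'simulate' with "
                    "a suitable visit schedule")
        metrics = {}
        for target in targets:
            for feature_set in config.feature_sets:
                res = nested_loso_evaluate(
                    table, target=target, feature_set=feature_set, mode=mode,
                    horizon_months=config.horizon_months, spec=spec,
                    max_subset_size=config.max_subset_size)
                key = f"{target}_{feature_set}"
                metrics[key] = {
                    "r2": res.r2, "rmse": res.rmse,
                    "selected_subset": list(res.selected_subset),
                    "subset_frequency": res.subset_frequency,
                    "n_rows": int(len(res.predictions)),
                }
                res.predictions.to_csv(out_dir / f"predictions_{recipe}_{key}.csv",
                                       index=False, float_format="%.6f")
        _dump_json(metrics, out_dir / f"metrics_{recipe}.json")
        _write_manifest(out_dir, config, recipe)
        return metrics

    if recipe == "learning_curve":
        n = table.df.loc[np.isfinite(table.df["SARA"]), "subject_id"].nunique()
        ks = tuple(config.learning_curve_k) or tuple(range(4, n + 1, 2))
        out = {}
        for target in config.targets:
            lc = learning_curve(table, target=target, k_values=ks, spec=spec,
                                seed=config.seed,
                                feature_set=config.feature_sets[0],
                                n_combinations_max=config.learning_curve_max_combinations)
            lc.as_frame().to_csv(out_dir / f"learning_curve_{target}.csv", index=False,
                                 float_format="%.6f")
            out[target] = lc.as_frame().to_dict(orient="list")
        _dump_json(out, out_dir / "metrics_learning_curve.json")
        _write_manifest(out_dir, config, recipe)
        return out

    # validate_features
    rt = test_retest_correlation(table)
    rt.to_csv(out_dir / "test_retest.csv", float_format="%.6f")
    screens = {}
    for col in table.feature_columns("8MW") + table.feature_columns("9HPT"):
        try:
            stat, p = group_difference_screen(table, col)
            screens[col] = {"kruskal_stat": stat, "p": p}
        except ValueError:
            screens[col] = {"kruskal_stat": float("nan"), "p": float("nan")}
    _dump_json({"median_test_retest_r": float(np.nanmedian(rt.values)),
                "screens": screens}, out_dir / "metrics_validate_features.json")
    _write_manifest(out_dir, config, recipe)
    return {"median_test_retest_r": float(np.nanmedian(rt.values))}
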