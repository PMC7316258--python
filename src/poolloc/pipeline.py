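"""End-to-end pipeline driver.

Runs synthesize -> simulate -> extract -> band-pass -> featurize ->
split -> train (forest, feature reduction, classifier suite, GP
regression standard and leave-location-out) -> optional SRP baseline ->
evaluate, and writes the result tables.  Recordings are processed one at
a time (only the 897,856-float feature row is kept per snippet), so the
memory footprint stays flat regardless of dataset size.

All randomness derives from a single `seed` config field.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    DEFAULT_HYDROPHONES,
    DEFAULT_SOURCE_LOCATIONS,
    EnvironmentConfig,
    HydrophoneGeometry,
)
from .tonals import TonalSpec, build_parameter_grid
from .simulate import SimulationConfig, dataset_manifest, \
    iter_synthetic_recordings
from .snippets import bandpass_snippet, detect_leader_tones, \
    extract_snippet, split_train_test
from .features import SnippetFeaturizer
from .models import (
    GaussianProcessLocalizer,
    RandomForestLocalizer,
    leave_location_out_eval,
    parsimonious_analysis,
    train_classifiers,
)
from .baselines import SRPConfig, srp_localize
from .evaluate import accuracy_with_wilson, deviations, error_summary_table

__all__ = ["PipelineConfig", "PipelineResult", "select_tonal_subset",
           "run_pipeline", "extract_features"]

log = logging.getLogger("poolloc")


@dataclass
class PipelineConfig:
    """One config object drives the whole run; see field comments."""

    seed: int = 0
    n_tonal_groups: int | None = 8   # sibling pairs per location; None = 64
    max_reflection_order: int = 2
    noise_rms: float = 0.1           # 0.1 -> 20 dB SNR
    test_fraction: float = 0.10
    n_trees: int = 300
    gpr_restarts: int = 1
    run_leave_out: bool = True
    run_parsimonious: bool = True
    srp_max_snippets: int = 0        # SRP on at most this many test snippets
    srp_cube_edge: float = 0.15
    location_ids: list[str] | None = None   # subset of P1..P14; None = all
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        if not os.path.exists(path):
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    manifest: pd.DataFrame
    partition: object
    forest: RandomForestLocalizer
    reduced_indices: np.ndarray
    suite: object
    gpr: GaussianProcessLocalizer
    classification_table: pd.DataFrame
    regression_table: pd.DataFrame
    parsimonious: object | None = None
    srp_predictions: pd.DataFrame | None = None


def select_tonal_subset(specs: list[TonalSpec], n_groups: int | None
                        ) -> list[TonalSpec]:
    """Deterministic sibling-pair subset: every 64/n_groups-th parameter
    permutation, so the fastest-varying parameters are held fixed and the
    slow ones (duration, cycle count, center frequency) vary first."""
    if n_groups is None:
        return list(specs)
    groups = sorted({s.sibling_group for s in specs})
    if not 1 <= n_groups <= len(groups):
        raise ValueError(f"n_groups must be in [1, {len(groups)}]")
    stride = len(groups) // n_groups
    chosen = {groups[i * stride] for i in range(n_groups)}
    return [s for s in specs if s.sibling_group in chosen]


def extract_features(
    manifest: pd.DataFrame,
    specs: list[TonalSpec],
    geometry: HydrophoneGeometry | None = None,
    env: EnvironmentConfig | None = None,
    sim: SimulationConfig | None = None,
    featurizer: SnippetFeaturizer | None = None,
    srp_files: set | None = None,
    srp_cfg: SRPConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate, window, band-pass and featurize every manifest row.

    Streams one recording at a time.  If `srp_files` is given, snippets
    whose manifest `file` is in it are additionally localized with SRP
    and the predictions returned in the second frame.
    """
    env = env or EnvironmentConfig()
    geometry = geometry or DEFAULT_HYDROPHONES
    featurizer = featurizer or SnippetFeaturizer()
    by_id = {s.tonal_id: s for s in specs}
    X = np.empty((len(manifest), featurizer.n_features), dtype=np.float32)
    srp_rows = []
    for r, (row, rec) in enumerate(
        iter_synthetic_recordings(manifest, specs, geometry, env, sim)
    ):
        spec = by_id[row["tonal_id"]]
        onsets = detect_leader_tones(rec)
        if not onsets:
            raise RuntimeError(
                f"no leader tone detected for {row['file']}"
            )
        snip = extract_snippet(rec, onsets[0], spec, row["location_id"],
                               (row["x"], row["y"], row["z"]))
        snip = bandpass_snippet(snip, spec)
        X[r] = featurizer.transform_one(snip)
        if srp_files and row["file"] in srp_files:
            pt, info = srp_localize(snip, geometry, env, srp_cfg)
            srp_rows.append({"id": row["file"], "x": pt[0], "y": pt[1],
                             "z": pt[2], "score": info["score"]})
    return X, pd.DataFrame(srp_rows)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full study pipeline at the configured scale."""
    rng_seed = cfg.seed
    env = EnvironmentConfig()
    geometry = DEFAULT_HYDROPHONES
    locations = [
        loc for loc in DEFAULT_SOURCE_LOCATIONS
        if cfg.location_ids is None or loc.id in cfg.location_ids
    ]
    if cfg.location_ids is not None and len(locations) != len(
        cfg.location_ids
    ):
        raise ValueError("unknown location id in config")
    sim = SimulationConfig(
        max_reflection_order=cfg.max_reflection_order,
        noise_rms=cfg.noise_rms,
        rng_seed=rng_seed,
    )
    specs = select_tonal_subset(build_parameter_grid(), cfg.n_tonal_groups)
    log.info("stage synthesize/simulate: %d tonals x %d locations",
             len(specs), len(locations))
    manifest = dataset_manifest(specs, locations, sim)
    partition = split_train_test(manifest, cfg.test_fraction, rng_seed)

    srp_files = set(partition.test_ids[: cfg.srp_max_snippets])
    featurizer = SnippetFeaturizer()
    log.info("stage featurize: %d snippets", len(manifest))
    X, srp_preds = extract_features(
        manifest, specs, geometry, env, sim, featurizer,
        srp_files or None, SRPConfig(cube_edge=cfg.srp_cube_edge),
    )

    files = manifest["file"].to_numpy()
    is_test = np.isin(files, partition.test_ids)
    y = manifest["location_id"].to_numpy()
    coords = manifest[["nominal_x", "nominal_y", "nominal_z"]].to_numpy()

    log.info("stage train: random forest (%d trees)", cfg.n_trees)
    forest = RandomForestLocalizer(
        n_trees=cfg.n_trees, random_state=rng_seed
    ).fit(X[~is_test], y[~is_test])
    reduced = forest.reduced_indices_
    if reduced.size == 0:
        raise RuntimeError("stage train: empty reduced feature set")
    rf_test_pred = forest.predict(X[is_test])
    Xr_train = np.ascontiguousarray(X[np.ix_(~is_test, reduced)])
    Xr_test = np.ascontiguousarray(X[np.ix_(is_test, reduced)])

    log.info("stage train: classifier suite on %d features", reduced.size)
    suite = train_classifiers(Xr_train, y[~is_test], seed=rng_seed)

    cls_rows = []
    acc, ci = accuracy_with_wilson(rf_test_pred, y[is_test])
    cls_rows.append({"model": "RF", "cv_accuracy_pct": np.nan,
                     "oob_accuracy_pct": 100 * forest.oob_score_,
                     "test_accuracy_pct": acc,
                     "wilson_low": ci[0], "wilson_high": ci[1],
                     "n_test": int(is_test.sum())})
    for name, model in suite.models.items():
        pred = model.predict(Xr_test)
        acc, ci = accuracy_with_wilson(pred, y[is_test])
        cls_rows.append({"model": name,
                         "cv_accuracy_pct": 100 * suite.cv_accuracy[name],
                         "oob_accuracy_pct": np.nan,
                         "test_accuracy_pct": acc,
                         "wilson_low": ci[0], "wilson_high": ci[1],
                         "n_test": int(is_test.sum())})
    classification_table = pd.DataFrame(cls_rows)

    log.info("stage train: Gaussian process regression")
    gpr = GaussianProcessLocalizer(
        n_restarts=cfg.gpr_restarts, random_state=rng_seed
    ).fit(Xr_train, coords[~is_test])
    truth = pd.DataFrame({"id": files[is_test],
                          "x": coords[is_test, 0],
                          "y": coords[is_test, 1],
                          "z": coords[is_test, 2]})
    dev_frames = {}
    pred_s = gpr.predict(Xr_test)
    dev_frames["S GR"] = deviations(
        pd.DataFrame({"id": files[is_test], "x": pred_s[:, 0],
                      "y": pred_s[:, 1], "z": pred_s[:, 2]}), truth)
    if cfg.run_leave_out:
        log.info("stage train: leave-location-out regression")
        pred_lo, _ = leave_location_out_eval(
            Xr_train, coords[~is_test], y[~is_test],
            Xr_test, coords[is_test], y[is_test],
            seed=rng_seed, n_restarts=cfg.gpr_restarts,
        )
        dev_frames["LO GR"] = deviations(
            pd.DataFrame({"id": files[is_test], "x": pred_lo[:, 0],
                          "y": pred_lo[:, 1], "z": pred_lo[:, 2]}), truth)
    if len(srp_preds):
        dev_frames["SRP"] = deviations(
            srp_preds[["id", "x", "y", "z"]],
            truth[truth["id"].isin(srp_preds["id"])],
        )
    regression_table = error_summary_table(dev_frames)

    pars = None
    if cfg.run_parsimonious:
        log.info("stage analyze: parsimonious tree")
        index_map = featurizer.index_map()
        pairs = index_map.pairs(reduced)
        arr_names = geometry.array_ids
        arr_of_ch = np.array([sorted(set(arr_names)).index(a)
                              for a in arr_names])
        pars = parsimonious_analysis(
            suite.models["tree"], Xr_train, y[~is_test],
            pairs, arr_of_ch, seed=rng_seed, n_trees=cfg.n_trees,
        )
        pars.test_accuracy = float(np.mean(
            pars.forest.predict(Xr_test[:, pars.used_indices]) == y[is_test]
        ))

    result = PipelineResult(
        manifest=manifest, partition=partition, forest=forest,
        reduced_indices=reduced, suite=suite, gpr=gpr,
        classification_table=classification_table,
        regression_table=regression_table,
        parsimonious=pars,
        srp_predictions=srp_preds if len(srp_preds) else None,
    )
    if cfg.out_dir:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, res: PipelineResult) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)
    res.manifest.to_csv(os.path.join(cfg.out_dir, "manifest.csv"),
                        index=False)
    res.partition.to_json(os.path.join(cfg.out_dir, "partition.json"))
    res.classification_table.to_csv(
        os.path.join(cfg.out_dir, "classification.csv"), index=False)
    res.regression_table.to_csv(
        os.path.join(cfg.out_dir, "regression.csv"), index=False)
    if res.srp_predictions is not None:
        res.srp_predictions.to_csv(
            os.path.join(cfg.out_dir, "srp_predictions.csv"), index=False)
    with open(os.path.join(cfg.out_dir, "run_info.json"), "w") as fh:
        json.dump({"config": asdict(cfg),
                   "n_reduced_features": int(res.reduced_indices.size),
                   "oob_accuracy": res.forest.oob_score_},
                  fh, indent=2, default=str)
    log.info("wrote result tables to %s", cfg.out_dir)
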