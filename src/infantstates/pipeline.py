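"""End-to-end orchestration: ingest -> preprocess -> PM -> select -> fit ->
decode -> metrics -> association, with a machine-readable run manifest.

The configuration is a plain nested dict (typically loaded from YAML by
the CLI).  Every stage writes its artefact under the output directory;
excluded videos are logged with the reason.  A stage failure raises with
the stage name and, where known, the offending video id.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import arhmm, association, model_selection, preprocess, state_metrics
from .keypoint_io import read_cohort_table, read_keypoint_table
from .preprocess import PreprocessConfig
from .principal_movements import fit_pm_basis, project

log = logging.getLogger("infantstates")

REQUIRED_KEYS = ("input_dir", "output_dir", "seed")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "preprocess": {},
    "pm": {"n_videos": 100, "k": 15},
    "selection": {
        "folds": 5,
        "grid": [["arhmm", K, L] for K in (1, 2, 5, 8, 10, 15) for L in (1, 2)],
        "rule": "test_ll",
        "max_iter": 100,
    },
    "fit": {"repeats": 25, "max_iter": 500},
    "association": {"response": "bout_count", "terms": ["age", "birth", "gma"], "alpha": 0.05},
}


def _merged(config: dict) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def validate_config(config: dict) -> dict:
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    return _merged(config)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, video_id: str | None, cause: Exception):
        msg = f"stage {stage!r} failed"
        if video_id:
            msg += f" on video {video_id!r}"
        super().__init__(f"{msg}: {cause}")
        self.stage = stage
        self.video_id = video_id


def run_all(config: dict) -> Path:
    """Execute the full analysis described by ``config``; returns output dir."""
    config = validate_config(config)
    rng_seed = int(config["seed"])
    in_dir = Path(config["input_dir"])
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # ingest ---------------------------------------------------------------
    cohort = read_cohort_table(in_dir / "cohort.csv")
    fps_map = {}
    manifest_path = in_dir / "manifest.json"
    if manifest_path.exists():
        fps_map = json.loads(manifest_path.read_text()).get("fps", {})
    trajectories = []
    for _, row in cohort.frame.iterrows():
        vid = row["video_id"]
        path = in_dir / f"{vid}.csv"
        try:
            trajectories.append(
                read_keypoint_table(
                    path,
                    video_id=vid,
                    participant_id=row["participant_id"],
                    fps=float(fps_map.get(vid, 25.0)),
                )
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("ingest", vid, exc) from exc

    # preprocess -----------------------------------------------------------
    cfg = PreprocessConfig(**config["preprocess"])
    try:
        results, stats = preprocess.preprocess_cohort(trajectories, cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", None, exc) from exc
    stats.to_frame().to_csv(out_dir / "cohort_stats.csv", index=False)
    exclusions = [
        {"video_id": t.video_id, "reason": r.excluded_reason,
         "labelled_fraction": r.report.labelled_fraction}
        for t, r in zip(trajectories, results)
        if r.pose is None
    ]
    pd.DataFrame(exclusions).to_csv(out_dir / "exclusions.csv", index=False)
    poses = [r.pose for r in results if r.pose is not None]
    kept_ids = [p.video_id for p in poses]
    pid_of = dict(zip(cohort.frame["video_id"], cohort.frame["participant_id"]))
    log.info("preprocess: kept %d/%d videos", len(poses), len(trajectories))

    # principal movements --------------------------------------------------
    pm_cfg = config["pm"]
    n_fit = min(pm_cfg["n_videos"], len({pid_of[v] for v in kept_ids}))
    try:
        basis = fit_pm_basis(
            poses, n_videos=n_fit, participant_ids=pid_of, seed=rng_seed
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("pm", None, exc) from exc
    basis.save(out_dir / "pm_basis.json")
    k = int(pm_cfg["k"])
    series = [project(p, basis, k=k) for p in poses]

    # model selection ------------------------------------------------------
    sel = config["selection"]
    one_per, seen = [], set()
    for s in series:
        pid = pid_of[s.video_id]
        if pid not in seen:
            seen.add(pid)
            one_per.append(s)
    grid = [tuple(cell) for cell in sel["grid"]]
    try:
        table = model_selection.cv_grid_search(
            one_per,
            grid=grid,
            folds=int(sel["folds"]),
            seed=rng_seed,
            max_iter=int(sel["max_iter"]),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("select", None, exc) from exc
    table.to_csv(out_dir / "selection_table.csv", index=False)
    model_class, K, L = model_selection.select_best(table, rule=sel["rule"])
    log.info("selected %s with K=%d, L=%d", model_class, K, L)

    # final fit ------------------------------------------------------------
    fit_cfg = config["fit"]
    try:
        params = model_selection.refit_and_average(
            series, model_class, K, L,
            repeats=int(fit_cfg["repeats"]),
            max_iter=int(fit_cfg["max_iter"]),
            seed=rng_seed,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", None, exc) from exc
    params.save(out_dir / "model.json")

    # decode + metrics -----------------------------------------------------
    summaries = []
    labels = []
    disps = []
    for s, p in zip(series, poses):
        try:
            dec = arhmm.posterior_decode(params, s.velocity, video_id=s.video_id)
        except Exception as exc:  # noqa: BLE001
            raise StageError("decode", s.video_id, exc) from exc
        labels.append(dec.labels)
        disps.append(state_metrics.bodypoint_displacements(p.coords))
        summaries.append(state_metrics.summarise_video(dec.labels, params.K, s.video_id))
    summary_df = state_metrics.summaries_to_frame(summaries)
    summary_df.to_csv(out_dir / "state_summaries.csv", index=False)
    # decoded velocity labels and frame-to-frame displacements share the
    # same (t -> t+1) indexing on the 10 Hz grid
    hv = state_metrics.high_velocity_by_state(disps, labels, params.K)
    hv.to_csv(out_dir / "high_velocity.csv", index=False)

    # association ----------------------------------------------------------
    ac = config["association"]
    try:
        res = association.fit_state_lme(
            summary_df, cohort.frame,
            response=ac["response"], fixed_terms=tuple(ac["terms"]),
        )
        res = association.bonferroni(res, alpha=float(ac["alpha"]), K=params.K)
    except Exception as exc:  # noqa: BLE001
        raise StageError("assoc", None, exc) from exc
    res.to_csv(out_dir / "associations.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "config": config,
        "seed": rng_seed,
        "selected": {"model_class": model_class, "K": K, "L": L},
        "n_videos_in": len(trajectories),
        "n_videos_kept": len(poses),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
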