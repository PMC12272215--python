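"""End-to-end orchestration: synthesis -> preprocessing -> covariances ->
cross-validated age model -> interpretation."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as F
from . import interpret as I
from . import model as M
from . import preprocess as P
from .eegio import RunConfig
from .synth import GeneratorConfig, generate_cohort

logger = logging.getLogger("eegage")


def covariances_for_recording(rec, with_cross: bool = False):
    """Preprocess one recording and return its covariance structure.

    Meditation -> a single :class:`CovarianceSet`; sleep -> a stage ->
    CovarianceSet-or-None mapping.  Returns None if the recording is too
    short or retains no windows.
    """
    ws = P.preprocess_or_none(rec)
    if ws is None or ws.n_retained == 0:
        return None
    band_windows = F.apply_filterbank(ws)
    try:
        if rec.modality == "sleep":
            return F.sleep_stage_covariances(band_windows, with_cross=with_cross)
        return F.recording_covariances(band_windows, with_cross=with_cross)
    except ValueError:
        return None


def cohort_covariances(config: GeneratorConfig, with_cross: bool = False):
    """Generate a cohort in memory and compute per-recording covariances.

    Returns (cov_sets, meta) where ``meta`` has one row per usable
    recording (subject_id, session_id, age, date).
    """
    cov_sets, rows = [], []
    for meta, rec in generate_cohort(config):
        covs = covariances_for_recording(rec, with_cross=with_cross)
        if covs is None:
            logger.warning("dropping %s/%s: no usable windows", rec.subject_id, rec.session_id)
            continue
        cov_sets.append(covs)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "session_id": rec.session_id,
                "age": rec.age,
                "date": rec.date,
            }
        )
    return cov_sets, pd.DataFrame(rows)


def run_experiment(run: RunConfig, gen_config: GeneratorConfig | None = None) -> dict:
    """Execute one experiment track and write the result bundle.

    Writes eval.json, importance.csv, predictions.csv, and (for
    longitudinal cohorts) timelines.csv into ``run.out_dir``.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = gen_config or GeneratorConfig(
        n_subjects=run.n_subjects, modality=run.modality, seed=run.seed
    )
    logger.info("synthesizing %d-subject %s cohort (seed %d)", cfg.n_subjects, cfg.modality, cfg.seed)
    with_cross = run.variant == "cross-spectro-spatial"
    cov_sets, meta = cohort_covariances(cfg, with_cross=with_cross)
    logger.info("usable recordings: %d", len(meta))

    result = M.monte_carlo_cv(
        cov_sets,
        meta["age"].to_numpy(),
        meta["subject_id"].to_numpy(),
        variant=run.variant,
        modality=run.modality,
        n_splits=run.n_splits,
        test_frac=run.test_frac,
        seed=run.seed,
        keep_models=True,
        session_ids=meta["session_id"].to_numpy(),
    )
    summary = result.summary()
    logger.info("median R^2 %.3f (dummy %.3f), median MAE %.2f",
                summary["median_r2"], summary["median_dummy_r2"], summary["median_mae"])

    by = "band" if run.modality == "meditation" else "band-stage"
    n_imp_splits = min(10, len(result.artifacts))
    imp = I.importance_over_splits(
        M.EvalResult(result.per_split, result.predictions, result.artifacts[:n_imp_splits]),
        by=by,
        n_repeats=run.n_repeats_importance,
        seed=run.seed,
    )

    payload = {
        "config": {"modality": run.modality, "variant": run.variant,
                   "n_subjects": cfg.n_subjects, "seed": run.seed,
                   "n_splits": run.n_splits, "test_frac": run.test_frac},
        "summary": summary,
        "per_split": result.per_split.drop(columns=["test_subjects"]).to_dict("records"),
    }
    (out / "eval.json").write_text(json.dumps(payload, indent=2))
    imp.table.to_csv(out / "importance.csv", index=False)
    result.predictions.to_csv(out / "predictions.csv", index=False)

    outputs = {"summary": summary, "importance": imp.table, "predictions": result.predictions}

    if cfg.n_sessions >= 3:
        preds = result.predictions.merge(
            meta[["subject_id", "session_id", "date"]].drop_duplicates(),
            on=["subject_id", "session_id"], how="left",
        )
        timelines = []
        for sid, grp in preds.groupby("subject_id"):
            if len(grp) >= 3:
                timelines.append(I.longitudinal_summary(grp, subject_id=str(sid)))
        rows = [
            {"subject_id": t.subject_id, "slope_per_day": t.slope_per_day,
             "within_sd": t.within_sd, "n_sessions": len(t.sessions)}
            for t in timelines
        ]
        pd.DataFrame(rows).to_csv(out / "timelines.csv", index=False)
        outputs["timelines"] = pd.DataFrame(rows)

    return outputs
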