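"""Model interpretation: grouped permutation importance and longitudinal
brain-age-delta summaries.

Permutation importance jointly shuffles all test-set coordinates of one
feature group (a frequency band, or a band x sleep-stage combination)
across rows and records the drop in R^2; groups whose destruction hurts
the model most carry the age signal.  Values are normalized within a
run by the largest group-wise mean importance, so the top group scores
exactly 1.

The longitudinal side summarises the brain-age delta (predicted minus
chronological age) of subjects with many dated sessions: an ordinary
least-squares trend in delta per day and the within-subject spread,
compared against the cross-subject spread of a cross-sectional cohort
(trait- vs state-like variability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EvalResult, ModelBundle, r2_score


@dataclass
class ImportanceResult:
    """Mean/SD performance drop per feature group, with normalization."""

    table: pd.DataFrame  # columns: group, delta_r2, sd, normalized

    def top_group(self) -> str:
        return str(self.table.loc[self.table["delta_r2"].idxmax(), "group"])


def feature_groups(index: list[tuple], by: str = "band") -> dict[str, np.ndarray]:
    """Partition a feature index into coordinate groups.

    ``by='band'`` groups by frequency band; ``by='band-stage'`` by the
    (band, sleep stage) pair.  ``index`` entries are (band, stage,
    element) triples as produced by feature assembly.
    """
    groups: dict[str, list[int]] = {}
    for pos, (band, stage, _el) in enumerate(index):
        if by == "band":
            key = str(band)
        elif by == "band-stage":
            key = f"{band}/{stage}"
        else:
            raise ValueError("grouping must be 'band' or 'band-stage'")
        groups.setdefault(key, []).append(pos)
    return {k: np.asarray(v) for k, v in groups.items()}


def permutation_importance(
    bundle: ModelBundle,
    X_test: np.ndarray,
    y_test: np.ndarray,
    groups: dict[str, np.ndarray],
    n_repeats: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Grouped permutation importance on held-out rows.

    Per repetition, all coordinates of a group are jointly row-shuffled
    and Delta R^2 = R^2(intact) - R^2(permuted) is recorded; the table
    reports mean and SD over repetitions, plus means normalized by the
    largest group-wise mean (top group = 1).
    """
    for name, cols in groups.items():
        if len(cols) == 0:
            raise ValueError(f"feature group {name!r} has no coordinates")
    rng = np.random.default_rng(seed)
    base = r2_score(y_test, bundle.predict(X_test))
    n = X_test.shape[0]
    rows = []
    for name, cols in groups.items():
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            perm = rng.permutation(n)
            X_perm = X_test.copy()
            X_perm[:, cols] = X_perm[perm][:, cols]
            drops[r] = base - r2_score(y_test, bundle.predict(X_perm))
        rows.append({"group": name, "delta_r2": drops.mean(), "sd": drops.std(ddof=0)})
    table = pd.DataFrame(rows)
    return ImportanceResult(table=normalize_importance(table))


def normalize_importance(table: pd.DataFrame) -> pd.DataFrame:
    """Divide mean importances by the largest group-wise mean (idempotent)."""
    out = table.copy()
    top = out["delta_r2"].max()
    out["normalized"] = out["delta_r2"] / top if top > 0 else np.nan
    return out


def importance_over_splits(
    result: EvalResult,
    by: str = "band",
    n_repeats: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Average grouped importance over the fitted CV splits.

    Requires ``monte_carlo_cv(..., keep_models=True)``.  One fitted
    bundle per split is re-used; shuffling happens on that split's test
    rows only.  Mean importances are averaged across splits and then
    normalized; the SD column reports spread across splits and
    repetitions combined.
    """
    if not result.artifacts:
        raise ValueError("EvalResult has no stored models; rerun with keep_models=True")
    tables = []
    for k, art in enumerate(result.artifacts):
        bundle = art["bundle"]
        groups = feature_groups(bundle.feature_index, by=by)
        imp = permutation_importance(
            bundle, art["X_test"], art["y_test"], groups,
            n_repeats=n_repeats, seed=seed + k,
        )
        tables.append(imp.table[["group", "delta_r2", "sd"]])
    stacked = pd.concat(tables)
    agg = stacked.groupby("group", sort=False).agg(
        delta_r2=("delta_r2", "mean"), sd=("delta_r2", "std")
    ).reset_index()
    return ImportanceResult(table=normalize_importance(agg))


# ---------------------------------------------------------------------------
# brain-age delta and longitudinal summaries


def brain_age_delta(predictions: pd.DataFrame) -> pd.DataFrame:
    """Append the brain-age delta column: predicted minus chronological age."""
    out = predictions.copy()
    out["delta"] = out["y_pred"] - out["y"]
    return out


@dataclass
class SubjectTimeline:
    """Longitudinal delta summary for one subject."""

    subject_id: str
    sessions: pd.DataFrame  # date, days, y_pred, delta
    slope_per_day: float
    within_sd: float


def longitudinal_summary(sessions: pd.DataFrame, subject_id: str = "") -> SubjectTimeline:
    """OLS trend and spread of the brain-age delta across dated sessions.

    ``sessions`` needs columns date (ISO-8601), y, y_pred.  The slope is
    in years of delta per day, fitted on days since the first session.
    """
    if len(sessions) < 3:
        raise ValueError("longitudinal summary needs at least 3 dated sessions")
    df = brain_age_delta(sessions.sort_values("date").reset_index(drop=True))
    dates = pd.to_datetime(df["date"])
    days = (dates - dates.iloc[0]).dt.total_seconds().to_numpy() / 86400.0
    slope, _intercept = np.polyfit(days, df["delta"].to_numpy(), deg=1)
    df = df.assign(days=days)
    return SubjectTimeline(
        subject_id=subject_id or str(df.get("subject_id", pd.Series([""])).iloc[0]),
        sessions=df,
        slope_per_day=float(slope),
        within_sd=float(df["delta"].std(ddof=1)),
    )


def trait_state_ratio(
    cross_sectional: pd.DataFrame, timelines: list[SubjectTimeline]
) -> pd.DataFrame:
    """Within- vs cross-subject spread of the brain-age delta.

    A ratio well below 1 indicates the metric carries stable trait-like
    information on top of session-to-session state variability.
    """
    if len(cross_sectional) == 0 or len(timelines) == 0:
        raise ValueError("both tables must be non-empty")
    cross = brain_age_delta(cross_sectional)
    cross_sd = float(cross["delta"].std(ddof=1))
    within = float(np.mean([t.within_sd for t in timelines]))
    return pd.DataFrame(
        [
            {
                "mean_within_subject_sd": within,
                "cross_subject_sd": cross_sd,
                "ratio": within / cross_sd if cross_sd > 0 else np.inf,
            }
        ]
    )
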