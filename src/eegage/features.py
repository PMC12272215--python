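"""Filterbank covariance features and their vectorizations.

Three model variants, per recording:

* **spectral** -- log-diagonal of the nine per-band spatial covariance
  matrices (channel-wise log-powers), 4 x 9 = 36 coordinates;
* **spectro-spatial** -- Bures-Wasserstein tangent-space embedding of
  each per-band covariance at the per-band training barycenter,
  10 x 9 = 90 coordinates;
* **cross-spectro-spatial** -- tangent embedding of the single 36 x 36
  cross-spectral covariance (channels stacked across bands),
  36*37/2 = 666 coordinates.

For sleep, one covariance set is computed per sleep stage and the
per-stage vectors are concatenated in the fixed order (W, N1, N2, N3,
R), multiplying all lengths by five (180 / 450 / 3330).

Per-band covariances are estimated per retained window with OAS
shrinkage (well-conditioned even at 4 channels) and averaged
(Euclidean mean) across windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import oas as _sklearn_oas

from .containers import SLEEP_STAGES, WindowSet
from .filters import apply_fir, design_bandpass
from .riemann import (
    TangentPoint,
    tangent_embed,
    tangent_point,
    upper_vec_labels,
    wasserstein_mean,
)

VARIANTS = ("spectral", "spectro-spatial", "cross-spectro-spatial")

#: minimum retained windows for a sleep stage to count as observed
MIN_WINDOWS_PER_STAGE = 3


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered set of (name, low Hz, high Hz) band definitions."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"degenerate band {name}: ({low}, {high})")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)


#: the canonical nine-band filterbank, 0.1-49 Hz
DEFAULT_FILTERBANK = FilterBankSpec(
    bands=(
        ("low", 0.1, 1.0),
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha_low", 8.0, 10.0),
        ("alpha_mid", 10.0, 12.0),
        ("alpha_high", 12.0, 15.0),
        ("beta_low", 15.0, 26.0),
        ("beta_mid", 26.0, 35.0),
        ("beta_high", 35.0, 49.0),
    )
)


@dataclass
class CovarianceSet:
    """Per-band (and optionally cross-spectral) SPD matrices of one recording."""

    per_band: dict[str, np.ndarray]
    cross_spectral: np.ndarray | None = None
    stage: str | None = None
    n_windows_used: int = 0
    channel_names: tuple[str, ...] = ()


@dataclass
class TangentReference:
    """Barycenter reference points fitted on training recordings only."""

    per_band: dict[str, TangentPoint] = field(default_factory=dict)
    cross_spectral: TangentPoint | None = None
    fitted_on: str = ""


@dataclass
class FeatureVector:
    """Vectorized representation of one recording under one variant.

    ``index`` holds one (band, stage, element) label triple per
    coordinate.  Coordinates of unobserved sleep stages are NaN until
    dataset-level imputation (training-set means) fills them in;
    ``imputed_stages`` records which stages were missing.
    """

    values: np.ndarray
    index: list[tuple[str, str | None, str]]
    variant: str
    imputed_stages: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# filterbank and covariance estimation


def apply_filterbank(
    ws: WindowSet, spec: FilterBankSpec = DEFAULT_FILTERBANK
) -> dict[str, WindowSet]:
    """Produce one narrow-band copy of the windows per filterbank band.

    Kernels are capped at one window length so the low band remains
    realizable on 10 s windows (its transition is coarser than ideal at
    that resolution -- an inherent limit of short windows).
    """
    nyq = ws.sfreq / 2.0
    n_samples = ws.windows.shape[-1]
    out: dict[str, WindowSet] = {}
    for name, low, high in spec.bands:
        if high >= nyq:
            raise ValueError(f"band {name} ({low}-{high} Hz) exceeds Nyquist {nyq} Hz")
        kernel = design_bandpass(low, high, ws.sfreq, max_taps=n_samples)
        out[name] = ws.copy_with(windows=apply_fir(ws.windows, kernel))
    return out


def oas_covariance(samples: np.ndarray) -> np.ndarray:
    """Oracle Approximating Shrinkage covariance of channels x n samples.

    Returns (1-rho) S + rho (tr S / C) I with the closed-form OAS
    shrinkage weight; always symmetric positive definite.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be channels x n")
    c, n = samples.shape
    if n <= 1:
        raise ValueError("need more than one sample to estimate covariance")
    cov, _ = _sklearn_oas(samples.T, assume_centered=False)
    return 0.5 * (cov + cov.T)


def recording_covariances(
    band_windows: dict[str, WindowSet],
    with_cross: bool = False,
    stage: str | None = None,
) -> CovarianceSet:
    """Per-band covariance set of one recording (one stage for sleep).

    Per band: the Euclidean mean over retained windows of per-window OAS
    covariances.  With ``with_cross``, the narrow-band signals of every
    window are additionally stacked channel-wise (channels within band,
    bands in filterbank order) before covariance estimation, giving one
    C*|bands| square matrix averaged across windows.
    """
    names = list(band_windows)
    first = band_windows[names[0]]
    mask = first.retained.copy()
    if stage is not None:
        if first.stages is None:
            raise ValueError("stage-restricted covariances require stage labels")
        mask &= first.stages == stage
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        where = "" if stage is None else f" in stage {stage}"
        raise ValueError(f"no retained windows{where}")
    per_band: dict[str, np.ndarray] = {}
    for name in names:
        wins = band_windows[name].windows[idx]
        per_band[name] = np.mean([oas_covariance(w) for w in wins], axis=0)
    cross = None
    if with_cross:
        stacked = np.concatenate([band_windows[n].windows[idx] for n in names], axis=1)
        cross = np.mean([oas_covariance(w) for w in stacked], axis=0)
    return CovarianceSet(
        per_band=per_band,
        cross_spectral=cross,
        stage=stage,
        n_windows_used=int(idx.size),
        channel_names=tuple(first.channel_names),
    )


def sleep_stage_covariances(
    band_windows: dict[str, WindowSet],
    with_cross: bool = False,
    min_windows: int = MIN_WINDOWS_PER_STAGE,
) -> dict[str, CovarianceSet | None]:
    """One covariance set per sleep stage; None for unobserved stages."""
    first = band_windows[next(iter(band_windows))]
    if first.stages is None:
        raise ValueError("sleep covariances require stage labels")
    out: dict[str, CovarianceSet | None] = {}
    for stage in SLEEP_STAGES:
        n_stage = int(((first.stages == stage) & first.retained).sum())
        if n_stage < min_windows:
            out[stage] = None
        else:
            out[stage] = recording_covariances(band_windows, with_cross, stage=stage)
    return out


# ---------------------------------------------------------------------------
# vectorization


def log_diag_vectorize(cs: CovarianceSet) -> FeatureVector:
    """Eq.-style log-diagonal extraction: channel-wise log-powers per band."""
    values, index = [], []
    chans = list(cs.channel_names) or None
    for band, mat in cs.per_band.items():
        diag = np.diag(mat)
        if (diag <= 0).any():
            raise ValueError(f"non-positive diagonal in band {band}")
        values.append(np.log(diag))
        names = chans or [str(i) for i in range(mat.shape[0])]
        index.extend((band, cs.stage, ch) for ch in names)
    return FeatureVector(np.concatenate(values), index, "spectral")


def fit_tangent_reference(
    cov_sets: list[CovarianceSet],
    use_cross: bool = False,
    fitted_on: str = "",
) -> TangentReference:
    """Fit Bures-Wasserstein barycenter references on training recordings.

    For sleep, pass the flattened list of per-stage covariance sets; a
    single reference per band (pooled across stages) is fitted, which
    keeps the embedding comparable across stages.
    """
    ref = TangentReference(fitted_on=fitted_on)
    if use_cross:
        mats = [cs.cross_spectral for cs in cov_sets if cs.cross_spectral is not None]
        if not mats:
            raise ValueError("no cross-spectral covariances to fit the reference on")
        ref.cross_spectral = tangent_point(wasserstein_mean(mats))
    else:
        bands = list(cov_sets[0].per_band)
        for band in bands:
            mean = wasserstein_mean([cs.per_band[band] for cs in cov_sets])
            ref.per_band[band] = tangent_point(mean)
    return ref


def tangent_project(sigma: np.ndarray, reference: TangentPoint) -> np.ndarray:
    """Tangent-space block of one SPD matrix: d(d+1)/2 coordinates.

    Thin wrapper over :func:`eegage.riemann.tangent_embed`; the vector
    norm equals the Bures-Wasserstein distance to the reference.
    """
    return tangent_embed(sigma, reference)


def _cross_element_labels(band_names: list[str], channels: list[str]) -> list[str]:
    stacked = [f"{ch}_{band}" for band in band_names for ch in channels]
    return upper_vec_labels(len(stacked), stacked)


def _vectorize_one(
    cs: CovarianceSet, variant: str, ref: TangentReference | None
) -> FeatureVector:
    if variant == "spectral":
        return log_diag_vectorize(cs)
    if ref is None:
        raise ValueError(f"variant {variant!r} requires a fitted TangentReference")
    chans = list(cs.channel_names) or [str(i) for i in range(next(iter(cs.per_band.values())).shape[0])]
    if variant == "spectro-spatial":
        values, index = [], []
        for band, mat in cs.per_band.items():
            block = tangent_project(mat, ref.per_band[band])
            values.append(block)
            index.extend((band, cs.stage, el) for el in upper_vec_labels(mat.shape[0], chans))
        return FeatureVector(np.concatenate(values), index, variant)
    if variant == "cross-spectro-spatial":
        if cs.cross_spectral is None:
            raise ValueError("covariance set has no cross-spectral matrix")
        block = tangent_project(cs.cross_spectral, ref.cross_spectral)
        labels = _cross_element_labels(list(cs.per_band), chans)
        index = [("cross", cs.stage, el) for el in labels]
        return FeatureVector(block, index, variant)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def _nan_block_like(
    template: FeatureVector, stage: str
) -> FeatureVector:
    index = [(band, stage, el) for band, _, el in template.index]
    return FeatureVector(
        np.full(len(template), np.nan), index, template.variant, imputed_stages=(stage,)
    )


def assemble_features(
    covariances: CovarianceSet | dict[str, CovarianceSet | None],
    variant: str,
    modality: str,
    ref: TangentReference | None = None,
) -> FeatureVector:
    """Assemble the final feature vector of one recording.

    Meditation: a single covariance set -> 36 / 90 / 666 coordinates.
    Sleep: a stage -> covariance-set mapping; per-stage vectors are
    concatenated in the fixed stage order -> 180 / 450 / 3330
    coordinates.  Stages missing from the recording contribute NaN
    blocks (later imputed with training-set means) and are flagged.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if modality == "meditation":
        if isinstance(covariances, dict):
            raise ValueError("meditation assembly takes a single CovarianceSet")
        return _vectorize_one(covariances, variant, ref)

    if not isinstance(covariances, dict):
        raise ValueError("sleep assembly takes a stage -> CovarianceSet mapping")
    observed = {s: cs for s, cs in covariances.items() if cs is not None}
    if not observed:
        raise ValueError("recording has no observed sleep stage")
    template = _vectorize_one(next(iter(observed.values())), variant, ref)
    parts: list[FeatureVector] = []
    imputed: list[str] = []
    for stage in SLEEP_STAGES:
        cs = covariances.get(stage)
        if cs is None:
            parts.append(_nan_block_like(template, stage))
            imputed.append(stage)
        else:
            fv = _vectorize_one(cs, variant, ref)
            fv.index = [(band, stage, el) for band, _, el in fv.index]
            parts.append(fv)
    values = np.concatenate([p.values for p in parts])
    index = [lab for p in parts for lab in p.index]
    return FeatureVector(values, index, variant, imputed_stages=tuple(imputed))


def expected_length(variant: str, modality: str, n_channels: int = 4, n_bands: int = 9) -> int:
    """Feature-vector length for a variant/modality combination."""
    tri = n_channels * (n_channels + 1) // 2
    cross_dim = n_channels * n_bands
    per_stage = {
        "spectral": n_channels * n_bands,
        "spectro-spatial": tri * n_bands,
        "cross-spectro-spatial": cross_dim * (cross_dim + 1) // 2,
    }[variant]
    return per_stage * (5 if modality == "sleep" else 1)
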