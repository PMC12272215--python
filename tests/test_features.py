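"""Filterbank covariances, vectorizations, and assembly dimensions."""

import numpy as np
import pytest

import eegage as E
from eegage.containers import SLEEP_STAGES, WindowSet
from eegage.features import (
    DEFAULT_FILTERBANK,
    MIN_WINDOWS_PER_STAGE,
    CovarianceSet,
    log_diag_vectorize,
    oas_covariance,
    recording_covariances,
    sleep_stage_covariances,
)

from conftest import rand_spd

FS = 128.0


def tone_windows(freq, n_windows=4, seconds=10.0, sfreq=FS):
    t = np.arange(int(seconds * sfreq)) / sfreq
    win = np.tile(np.sin(2 * np.pi * freq * t), (4, 1))
    return WindowSet(windows=np.tile(win, (n_windows, 1, 1)), sfreq=sfreq,
                     window_length=seconds)


class TestFilterbank:
    def test_default_band_count(self):
        out = E.apply_filterbank(tone_windows(10.0))
        assert len(out) == 9
        assert list(out) == [b[0] for b in DEFAULT_FILTERBANK.bands]

    def test_tone_lands_in_its_band(self):
        out = E.apply_filterbank(tone_windows(11.0))
        p_mid = (out["alpha_mid"].windows ** 2).mean()
        p_beta = (out["beta_mid"].windows ** 2).mean()
        assert 10 * np.log10(p_mid / p_beta) >= 20

    def test_zero_input(self):
        ws = WindowSet(windows=np.zeros((2, 4, 1280)), sfreq=FS, window_length=10.0)
        for band in E.apply_filterbank(ws).values():
            np.testing.assert_array_equal(band.windows, 0.0)

    def test_band_above_nyquist(self):
        spec = E.FilterBankSpec(bands=(("hi", 60.0, 70.0),))
        with pytest.raises(ValueError, match="Nyquist"):
            E.apply_filterbank(tone_windows(10.0), spec)


class TestOASCovariance:
    def test_large_sample_consistency(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 100_000))
        np.testing.assert_allclose(oas_covariance(x), np.eye(4), atol=0.02)

    def test_small_sample_shrinks_toward_scaled_identity(self):
        rng = np.random.default_rng(1)
        true = np.diag([1.0, 2.0, 3.0, 4.0])
        x = np.linalg.cholesky(true) @ rng.standard_normal((4, 6))
        cov = oas_covariance(x)
        # heavy shrinkage: off-diagonals small relative to the mean variance
        mean_var = np.trace(cov) / 4
        assert np.abs(cov - np.diag(np.diag(cov))).max() < mean_var
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_rank_deficient_input_still_spd(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 500))
        x = np.vstack([x, x[0]])  # duplicated channel
        assert np.linalg.eigvalsh(oas_covariance(x)).min() > 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            oas_covariance(np.ones((4, 1)))


class TestRecordingCovariances:
    def test_cross_spectral_shape(self, meditation_covsets):
        assert meditation_covsets[0].cross_spectral.shape == (36, 36)

    def test_single_window_equals_its_oas(self):
        ws = tone_windows(10.0, n_windows=1)
        bands = E.apply_filterbank(ws)
        cs = recording_covariances(bands)
        for name, band_ws in bands.items():
            np.testing.assert_allclose(
                cs.per_band[name], oas_covariance(band_ws.windows[0]), atol=1e-12
            )

    def test_identical_windows_average_to_one(self):
        bands = E.apply_filterbank(tone_windows(10.0, n_windows=3))
        cs3 = recording_covariances(bands)
        one = E.apply_filterbank(tone_windows(10.0, n_windows=1))
        cs1 = recording_covariances(one)
        for name in cs3.per_band:
            np.testing.assert_allclose(cs3.per_band[name], cs1.per_band[name], atol=1e-10)

    def test_zero_retained_windows_error(self):
        ws = tone_windows(10.0, n_windows=2)
        ws.retained[:] = False
        with pytest.raises(ValueError, match="no retained windows"):
            recording_covariances(E.apply_filterbank(ws))

    def test_all_matrices_spd(self, sleep_covsets):
        for mapping in sleep_covsets:
            for cs in mapping.values():
                assert cs is not None
                for mat in cs.per_band.values():
                    assert np.linalg.eigvalsh(mat).min() > 0


class TestLogDiagonal:
    def _covset(self, per_band):
        return CovarianceSet(per_band=per_band, channel_names=("TP9", "Fp1", "Fp2", "TP10"))

    def test_identity_gives_zero_vector(self):
        cs = self._covset({b[0]: np.eye(4) for b in DEFAULT_FILTERBANK.bands})
        fv = log_diag_vectorize(cs)
        assert len(fv) == 36
        np.testing.assert_array_equal(fv.values, 0.0)

    def test_exponential_diagonal_block(self):
        per_band = {b[0]: np.eye(4) for b in DEFAULT_FILTERBANK.bands}
        per_band["theta"] = np.diag(np.exp([1.0, 2.0, 3.0, 4.0]))
        fv = log_diag_vectorize(self._covset(per_band))
        block = [v for v, lab in zip(fv.values, fv.index) if lab[0] == "theta"]
        np.testing.assert_allclose(block, [1, 2, 3, 4], atol=1e-12)

    def test_nonpositive_diagonal_rejected(self):
        per_band = {b[0]: np.eye(4) for b in DEFAULT_FILTERBANK.bands}
        per_band["delta"] = np.diag([1.0, -1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="non-positive"):
            log_diag_vectorize(self._covset(per_band))

    def test_channel_scaling_shifts_log_power(self):
        """Scaling channel c by g adds 2 log g to its coordinate in every band."""
        rng = np.random.default_rng(5)
        per_band = {b[0]: rand_spd(4, rng) for b in DEFAULT_FILTERBANK.bands}
        base = log_diag_vectorize(self._covset(per_band))
        g = 3.0
        scale = np.diag([1.0, g, 1.0, 1.0])
        scaled = {k: scale @ v @ scale for k, v in per_band.items()}
        shifted = log_diag_vectorize(self._covset(scaled))
        diff = shifted.values - base.values
        for d, (band, stage, el) in zip(diff, base.index):
            expected = 2 * np.log(g) if el == "Fp1" else 0.0
            assert d == pytest.approx(expected, abs=1e-10)


class TestAssemblyDimensions:
    @pytest.mark.parametrize(
        "variant,modality,expected",
        [
            ("spectral", "meditation", 36),
            ("spectro-spatial", "meditation", 90),
            ("cross-spectro-spatial", "meditation", 666),
            ("spectral", "sleep", 180),
            ("spectro-spatial", "sleep", 450),
            ("cross-spectro-spatial", "sleep", 3330),
        ],
    )
    def test_feature_lengths_match_model_table(
        self, variant, modality, expected,
        meditation_covsets, sleep_covsets, meditation_references, sleep_references,
    ):
        if modality == "meditation":
            covs, (ref_sp, ref_cs) = meditation_covsets[0], meditation_references
        else:
            covs, (ref_sp, ref_cs) = sleep_covsets[0], sleep_references
        ref = None if variant == "spectral" else (ref_cs if "cross" in variant else ref_sp)
        fv = E.assemble_features(covs, variant, modality, ref)
        assert len(fv) == expected == E.expected_length(variant, modality)
        assert len(fv.index) == expected
        assert np.isfinite(fv.values).all()

    def test_sleep_stage_order_fixed(self, sleep_covsets, sleep_references):
        fv = E.assemble_features(sleep_covsets[0], "spectral", "sleep")
        stages = [lab[1] for lab in fv.index]
        seen = list(dict.fromkeys(stages))
        assert seen == list(SLEEP_STAGES)

    def test_missing_stage_imputed_and_flagged(self, sleep_covsets):
        partial = dict(sleep_covsets[0])
        partial["R"] = None
        fv = E.assemble_features(partial, "spectral", "sleep")
        assert fv.imputed_stages == ("R",)
        assert len(fv) == 180
        r_block = np.array([v for v, lab in zip(fv.values, fv.index) if lab[1] == "R"])
        assert np.isnan(r_block).all()

    def test_unknown_variant(self, meditation_covsets):
        with pytest.raises(ValueError, match="unknown variant"):
            E.assemble_features(meditation_covsets[0], "quantum", "meditation")

    def test_tangent_variant_requires_reference(self, meditation_covsets):
        with pytest.raises(ValueError, match="TangentReference"):
            E.assemble_features(meditation_covsets[0], "spectro-spatial", "meditation")


class TestStageConditioning:
    def test_min_window_threshold(self):
        """Stages with fewer than the minimum retained windows are unobserved."""
        labels = ("W",) * 5 + ("N2",) * 2  # N2 below the threshold of 3
        rng = np.random.default_rng(9)
        wins = rng.normal(0, 10, (7, 4, 3840))
        ws = WindowSet(windows=wins, sfreq=FS, window_length=30.0,
                       stages=np.array(labels, dtype=object), modality="sleep")
        bands = E.apply_filterbank(ws)
        per_stage = sleep_stage_covariances(bands)
        assert per_stage["W"] is not None
        assert per_stage["N2"] is None
        assert all(per_stage[s] is None for s in ("N1", "N3", "R"))
        assert per_stage["W"].n_windows_used == 5
        assert MIN_WINDOWS_PER_STAGE == 3
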