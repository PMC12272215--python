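"""From one raw recording to the three covariance-based feature vectors.

Shows the preprocessing chain (crop, interpolation, filters, windowing,
250 uV rejection, 128 Hz resampling) and the three vectorizations with
their dimensions: log-diagonal (36), per-band tangent space (90), and
cross-spectral tangent space (666) for a 4-channel meditation recording.
"""

import numpy as np

import eegage as E
from eegage.pipeline import covariances_for_recording

cfg = E.GeneratorConfig(n_subjects=3, duration=180.0, seed=7, dropout_rate=0.005,
                        artifact_rate=3.0)
cohort = E.sample_cohort(cfg)

recs = [
    E.synthesize_recording(row, None, cfg, seed=np.random.SeedSequence([7, i]))
    for i, row in cohort.iterrows()
]
ws = E.preprocess_recording(recs[0])
print(f"windows: {ws.n_windows}, retained after 250 uV rejection: {ws.n_retained}, "
      f"sampling rate: {ws.sfreq:.0f} Hz")

covs = [covariances_for_recording(r, with_cross=True) for r in recs]
print(f"per-band covariance shape: {covs[0].per_band['alpha_mid'].shape}, "
      f"cross-spectral shape: {covs[0].cross_spectral.shape}")

ref_band = E.fit_tangent_reference(covs)
ref_cross = E.fit_tangent_reference(covs, use_cross=True)
for variant, ref in [("spectral", None), ("spectro-spatial", ref_band),
                     ("cross-spectro-spatial", ref_cross)]:
    fv = E.assemble_features(covs[0], variant, "meditation", ref)
    print(f"{variant:>22}: {len(fv):4d} features "
          f"(first 3: {np.round(fv.values[:3], 3)})")
# The three lengths (36 / 90 / 666) are the spectral, spectro-spatial
# and cross-spectro-spatial model inputs; for sleep each would be
# repeated once per stage (x5).
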