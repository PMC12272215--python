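"""File formats: EDF recordings, hypnogram/metadata CSVs, YAML configs.

EDF is the interchange format for raw recordings (16-bit samples,
physical unit microvolt, channel labels TP9/Fp1/Fp2/TP10).  Reading
goes through MNE; writing uses a small EDF writer implemented here.
Missing samples (NaN) are stored as the reserved digital minimum and
restored to NaN on read, so dropout masks survive a round trip.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DEFAULT_CHANNELS, Hypnogram, Recording

PHYS_MIN, PHYS_MAX = -2000.0, 2000.0  # microvolts
DIG_MIN, DIG_MAX = -32768, 32767
_MISSING_DIGITAL = DIG_MIN  # reserved sentinel for dropped samples
_SCALE = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)


def _pad(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (1 s data records, unit uV).

    The signal is truncated to whole seconds; finite values are clipped
    to the physical range minus a guard band so the missing-sample
    sentinel stays unambiguous.
    """
    path = Path(path)
    sfreq = int(round(rec.sfreq))
    n_records = rec.n_samples // sfreq
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_ch = rec.n_channels
    sig = rec.signal[:, : n_records * sfreq]
    missing = np.isnan(sig)
    clipped = np.clip(np.nan_to_num(sig), PHYS_MIN + 2 * _SCALE, PHYS_MAX)
    digital = np.round((clipped - PHYS_MIN) / _SCALE).astype(np.int64) + DIG_MIN
    digital = np.clip(digital, DIG_MIN + 1, DIG_MAX).astype(np.int16)
    digital[missing] = _MISSING_DIGITAL

    try:
        date = _dt.date.fromisoformat(rec.date) if rec.date else _dt.date(2023, 1, 1)
    except ValueError:
        date = _dt.date(2023, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id, 80),
            _pad(rec.session_id, 80),
            _pad(date.strftime("%d.%m.%y"), 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_ch + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    labels = [str(c) for c in rec.channel_names]
    header += b"".join(_pad(lab, 16) for lab in labels)
    header += b"".join(_pad("AgAgCl dry electrode", 80) for _ in labels)
    header += b"".join(_pad("uV", 8) for _ in labels)
    header += b"".join(_pad(f"{PHYS_MIN:.0f}", 8) for _ in labels)
    header += b"".join(_pad(f"{PHYS_MAX:.0f}", 8) for _ in labels)
    header += b"".join(_pad(str(DIG_MIN), 8) for _ in labels)
    header += b"".join(_pad(str(DIG_MAX), 8) for _ in labels)
    header += b"".join(_pad("", 80) for _ in labels)
    header += b"".join(_pad(str(sfreq), 8) for _ in labels)
    header += b"".join(_pad("", 32) for _ in labels)

    # records: per record, each channel's sfreq samples, int16 little-endian
    records = digital.reshape(n_ch, n_records, sfreq).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(records, dtype="<i2").tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE: (signal uV with NaN dropouts, sfreq, labels)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    # restore the missing-sample sentinel (digital minimum <-> physical minimum)
    data[data <= PHYS_MIN + 0.5 * _SCALE] = np.nan
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# cohort directory layout


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"epoch_index": range(len(hyp)), "stage": list(hyp.labels)}
    ).to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    return Hypnogram(labels=tuple(df.sort_values("epoch_index")["stage"].astype(str)))


def write_cohort_dir(config, out_dir: str | Path) -> pd.DataFrame:
    """Materialize a synthetic cohort: EDFs, hypnogram CSVs, metadata CSV.

    Returns the session-level metadata table that was written to
    ``metadata.csv`` (subject_id, session_id, age, sex, modality, date).
    """
    from .synth import generate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, rec in generate_cohort(config):
        stem = f"{rec.subject_id}_{rec.session_id}"
        write_edf(rec, out_dir / f"{stem}.edf")
        if rec.hypnogram is not None:
            write_hypnogram(rec.hypnogram, out_dir / f"{stem}_hypnogram.csv")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "session_id": rec.session_id,
                "age": rec.age,
                "sex": meta["sex"],
                "modality": rec.modality,
                "date": rec.date,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "metadata.csv", index=False)
    return table


def read_recording(path: str | Path, metadata: pd.DataFrame) -> Recording:
    """Load one EDF plus its metadata row (and hypnogram, if present)."""
    path = Path(path)
    stem = path.stem
    subject_id, _, session_id = stem.partition("_")
    row = metadata[
        (metadata["subject_id"] == subject_id) & (metadata["session_id"] == session_id)
    ]
    if row.empty:
        raise KeyError(f"no metadata row for session {stem!r}")
    row = row.iloc[0]
    signal, sfreq, labels = read_edf(path)
    hyp_path = path.with_name(f"{stem}_hypnogram.csv")
    hyp = read_hypnogram(hyp_path) if hyp_path.exists() else None
    return Recording(
        signal=signal,
        sfreq=sfreq,
        channel_names=labels,
        modality=str(row["modality"]),
        subject_id=subject_id,
        session_id=session_id,
        age=float(row["age"]),
        date=str(row["date"]),
        hypnogram=hyp,
    )


def load_cohort_dir(in_dir: str | Path):
    """Yield recordings from a cohort directory written by write_cohort_dir."""
    in_dir = Path(in_dir)
    metadata = pd.read_csv(in_dir / "metadata.csv")
    for path in sorted(in_dir.glob("*.edf")):
        yield read_recording(path, metadata)


# ---------------------------------------------------------------------------
# feature tables and run configuration


def write_feature_table(
    X: np.ndarray, index: list[tuple], meta: pd.DataFrame, path: str | Path
) -> Path:
    """Feature CSV (one row per recording) plus a JSON sidecar."""
    path = Path(path)
    cols = ["__".join(str(p) for p in lab if p is not None) for lab in index]
    df = pd.concat(
        [meta.reset_index(drop=True), pd.DataFrame(X, columns=cols)], axis=1
    )
    df.to_csv(path, index=False)
    sidecar = {
        "n_features": len(cols),
        "n_recordings": int(X.shape[0]),
        "columns_meta": list(meta.columns),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


@dataclass
class RunConfig:
    """End-to-end experiment configuration; defaults mirror the pipeline."""

    modality: str = "meditation"
    variant: str = "spectral"
    n_subjects: int = 60
    seed: int = 0
    n_splits: int = 100
    test_frac: float = 0.1
    crop_seconds: float = 60.0
    keep_seconds: float = 480.0
    ptp_threshold: float = 250.0
    resample_hz: float = 128.0
    n_repeats_importance: int = 100
    out_dir: str = "eegage_results"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
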