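"""Plain-text I/O: recording CSVs with YAML sidecars, cohort and epoch CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accelerometry import RawRecording


def write_recording_csv(rec: RawRecording, path: str | Path) -> list[Path]:
    """Write ``timestamp_iso8601,x_g,y_g,z_g`` plus a sidecar YAML.

    The sidecar (same stem, ``.yaml``) declares subject id, start time and
    sampling rate, which the CSV's timestamps alone cannot carry exactly.
    Returns [csv_path, sidecar_path].
    """
    path = Path(path)
    ts = rec.start_time + pd.to_timedelta(
        np.arange(rec.n_samples) / rec.sampling_rate_hz, unit="s"
    )
    df = pd.DataFrame(
        {
            "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x_g": rec.samples[:, 0],
            "y_g": rec.samples[:, 1],
            "z_g": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.5f")
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "subject_id": rec.subject_id,
                "start_time": str(rec.start_time),
                "sampling_rate_hz": float(rec.sampling_rate_hz),
                "n_samples": int(rec.n_samples),
            },
            sort_keys=False,
        )
    )
    return [path, sidecar]


def read_recording_csv(path: str | Path) -> RawRecording:
    """Read a recording CSV; the YAML sidecar supplies the sampling rate."""
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    df = pd.read_csv(path)
    samples = df[["x_g", "y_g", "z_g"]].to_numpy(dtype=np.float64)
    return RawRecording(
        subject_id=meta["subject_id"],
        start_time=pd.Timestamp(meta["start_time"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        samples=samples,
    )


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, float_format="%.2f")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_epochs_csv(epochs: pd.DataFrame, path: str | Path) -> None:
    """Write ``epoch_start,enmo_mg,wear`` (plus any annotation columns)."""
    epochs.to_csv(path, index=False, float_format="%.4f")


def read_epochs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["epoch_start"])
    if "wear" in df:
        df["wear"] = df["wear"].astype(bool)
    return df
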