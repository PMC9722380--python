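"""Raw tri-axial acceleration -> per-epoch ENMO with wear flags.

The signal chain: per-sample ENMO (Euclidean norm minus one gravitational
unit, negatives truncated to zero, expressed in milli-g), arithmetic-mean
aggregation into fixed 60-s epochs anchored at the recording start,
stationarity-based non-wear detection on a sliding window, and
valid-day / valid-subject filtering (>=10 h wear per calendar day,
>=4 valid days per subject).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .config import PipelineConfig, DEFAULT_CONFIG


@dataclass
class RawRecording:
    """Uniformly sampled tri-axial acceleration for one subject, in g.

    ``samples`` is an (n, 3) float array; sample *i* is taken at
    ``start_time + i / sampling_rate_hz`` seconds.
    """

    subject_id: str
    start_time: pd.Timestamp
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        # float32 is kept as-is (sufficient for mg-scale signals at half the
        # memory); anything else is promoted to float64
        self.samples = np.asarray(self.samples)
        if self.samples.dtype != np.float32:
            self.samples = self.samples.astype(np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def compute_enmo(raw: RawRecording) -> np.ndarray:
    """Per-sample ENMO in milli-g: ``max(0, ||a|| - 1) * 1000``.

    Raises ``ValueError`` naming the first offending index if any sample is
    non-finite. Rotation invariant by construction (depends on the norm only).
    """
    bad = ~np.isfinite(raw.samples).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite sample at index {int(np.argmax(bad))}")
    sq = np.einsum("ij,ij->i", raw.samples, raw.samples)
    mag = np.sqrt(sq, dtype=np.float64)
    return np.maximum(mag - 1.0, 0.0) * 1000.0


def aggregate_epochs(
    enmo_mg: np.ndarray,
    sampling_rate_hz: float,
    start_time: pd.Timestamp,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Mean-aggregate per-sample ENMO into complete epochs.

    Epoch boundaries are anchored at the recording start; a trailing
    incomplete epoch is discarded (no imputation). Returns a DataFrame with
    columns ``epoch_start`` (timestamp) and ``enmo_mg``.
    """
    spe = int(round(config.epoch_length_s * sampling_rate_hz))
    if spe <= 0:
        raise ValueError("epoch shorter than one sample")
    n_epochs = len(enmo_mg) // spe
    if n_epochs == 0:
        warnings.warn("fewer samples than one epoch; empty epoch series")
        return pd.DataFrame({"epoch_start": pd.DatetimeIndex([]), "enmo_mg": []})
    means = np.asarray(enmo_mg[: n_epochs * spe], dtype=np.float64).reshape(n_epochs, spe).mean(axis=1)
    starts = pd.Timestamp(start_time) + pd.to_timedelta(
        np.arange(n_epochs) * config.epoch_length_s, unit="s"
    )
    return pd.DataFrame({"epoch_start": starts, "enmo_mg": means})


def _block_stats(x: np.ndarray, block: int) -> tuple[np.ndarray, ...]:
    """Per-block (sum, sum of squares, min, max, count) along axis 0.

    Sums accumulate in float64 (the variance formula cancels catastrophically
    otherwise); a trailing partial block carries its true count.
    """
    n, n_axes = x.shape
    full = n // block
    tail = n - full * block
    n_blocks = full + (1 if tail else 0)
    s = np.empty((n_blocks, n_axes))
    s2 = np.empty((n_blocks, n_axes))
    mn = np.empty((n_blocks, n_axes), dtype=x.dtype)
    mx = np.empty((n_blocks, n_axes), dtype=x.dtype)
    cnt = np.full(n_blocks, block, dtype=np.int64)
    xb = x[: full * block].reshape(full, block, n_axes)
    s[:full] = xb.sum(axis=1, dtype=np.float64)
    s2[:full] = np.einsum("ijk,ijk->ik", xb, xb, dtype=np.float64)
    mn[:full] = xb.min(axis=1)
    mx[:full] = xb.max(axis=1)
    if tail:
        xt = x[full * block:]
        s[-1] = xt.sum(axis=0, dtype=np.float64)
        s2[-1] = np.einsum("jk,jk->k", xt, xt, dtype=np.float64)
        mn[-1] = xt.min(axis=0)
        mx[-1] = xt.max(axis=0)
        cnt[-1] = tail
    return s, s2, mn, mx, cnt


def detect_nonwear(
    raw: RawRecording, config: PipelineConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Per-epoch wear mask (True = worn) from a stationarity heuristic.

    Sliding windows of ``nonwear_window_min`` minutes advance in
    ``nonwear_step_min`` steps. Within a window an axis is stationary when
    its sample SD < 13 mg or its range < 50 mg; the window is non-wear when
    at least two of the three axes are stationary. Every complete epoch
    contained in a non-wear window is flagged non-wear. Extending a
    stationary gap can only flag more epochs (monotone).
    """
    fs = raw.sampling_rate_hz
    spe = int(round(config.epoch_length_s * fs))
    n_epochs = raw.n_samples // spe
    wear = np.ones(n_epochs, dtype=bool)

    win = int(round(config.nonwear_window_min * 60 * fs))
    step = int(round(config.nonwear_step_min * 60 * fs))
    if raw.n_samples < win:
        warnings.warn("recording shorter than one non-wear window; all epochs kept as wear")
        return wear

    # Combine per-step-block statistics into windows (window is a multiple
    # of the step, validated in config) -- exact and O(n).
    s, s2, mn, mx, cnt = _block_stats(raw.samples, step)
    bpw = win // step
    n_win = (raw.n_samples - win) // step + 1

    sd_thr = config.nonwear_sd_threshold_mg / 1000.0
    rng_thr = config.nonwear_range_threshold_mg / 1000.0

    epochs_per_win = config.nonwear_window_min * 60 // config.epoch_length_s
    epochs_per_step = config.nonwear_step_min * 60 // config.epoch_length_s
    for w in range(n_win):
        b0 = w  # window starts land on step-block boundaries
        S = s[b0 : b0 + bpw].sum(axis=0)
        S2 = s2[b0 : b0 + bpw].sum(axis=0)
        C = cnt[b0 : b0 + bpw].sum()
        var = np.maximum(S2 / C - (S / C) ** 2, 0.0)
        sd = np.sqrt(var)
        rng = mx[b0 : b0 + bpw].max(axis=0) - mn[b0 : b0 + bpw].min(axis=0)
        stationary = (sd < sd_thr) | (rng < rng_thr)
        if stationary.sum() >= 2:
            e0 = w * epochs_per_step
            wear[e0 : min(e0 + epochs_per_win, n_epochs)] = False
    return wear


def process_recording(
    raw: RawRecording, config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Full signal chain: ENMO -> epochs -> wear flags.

    Returns the epoch DataFrame with columns ``epoch_start, enmo_mg, wear``.
    """
    enmo = compute_enmo(raw)
    epochs = aggregate_epochs(enmo, raw.sampling_rate_hz, raw.start_time, config)
    wear = detect_nonwear(raw, config)
    epochs["wear"] = wear[: len(epochs)]
    return epochs


def mark_valid_days(
    epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG
) -> pd.Series:
    """Validity per local calendar day: wear minutes >= 600 (inclusive).

    Returns a boolean Series indexed by date. Days with no epochs at all do
    not appear; an empty day is invalid by absence.
    """
    if len(epochs) == 0:
        return pd.Series(dtype=bool)
    minutes_per_epoch = config.epoch_length_s / 60.0
    dates = epochs["epoch_start"].dt.normalize()
    wear_min = epochs.groupby(dates)["wear"].sum() * minutes_per_epoch
    valid = wear_min >= config.min_wear_min_per_day
    valid.index = valid.index.date
    valid.index.name = "date"
    valid.name = "valid"
    return valid


def is_valid_subject(
    valid_days: pd.Series, config: PipelineConfig = DEFAULT_CONFIG
) -> bool:
    """A subject is valid with at least ``min_valid_days`` valid days."""
    return int(valid_days.sum()) >= config.min_valid_days


def epoch_ecdf(epochs: pd.DataFrame):
    """Right-continuous empirical CDF over wear-epoch ENMO (milli-g).

    Returns a vectorised callable F with F(max) = 1. Raises ``ValueError``
    when no wear epoch is available.
    """
    vals = epochs.loc[epochs["wear"], "enmo_mg"].to_numpy()
    if vals.size == 0:
        raise ValueError("no wear epochs: ECDF undefined")
    cdf = _sps.ecdf(vals).cdf
    return lambda x: cdf.evaluate(np.asarray(x, dtype=float))
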