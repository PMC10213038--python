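"""Resting-state EEG preprocessing and relative band-power features.

The pipeline turns a raw 32-channel, 500 Hz recording into one
135-dimensional feature vector per session:

1. band-pass FIR filter, 1000 coefficients, 2-45 Hz, delay-compensated;
2. per-channel demean and linear detrend;
3. drop the four artifact-prone frontal channels (AF4, Fp2, Fp1, AF3);
4. flag 4-s epochs (50% overlap) containing any sample above 100 microvolts;
5. re-reference to Cz, then drop Cz (27 channels remain);
6. per retained epoch, Hann-windowed periodogram and relative band power in
   delta/theta/alpha/beta/gamma over the 2-45 Hz total;
7. elementwise median over epochs, renormalized per channel to sum to 1.

Relative powers are ratios, so the resulting features are invariant to any
positive rescaling of the input signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import SessionRecording
from .montage import BANDS, FRONTAL_DROP, REFERENCE, feature_names

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    taps: int = 1000
    lo_hz: float = 2.0
    hi_hz: float = 45.0
    window_s: float = 4.0
    overlap: float = 0.5
    amplitude_threshold_uv: float = 100.0
    drop_channels: tuple[str, ...] = FRONTAL_DROP
    reference: str = REFERENCE
    bands: tuple[tuple[str, float, float], ...] = BANDS


@dataclass
class CleanRecording:
    """Recording after channel exclusion and Cz re-referencing, with an
    epoch-level artifact rejection mask."""

    subject_id: str
    session_index: int
    channel_names: tuple[str, ...]
    fs: float
    data: np.ndarray                # (27, n_samples)
    epoch_slices: list[slice]
    retained: np.ndarray            # boolean, per epoch


@dataclass
class FeatureVector:
    """27 channels x 5 bands of relative band power for one session."""

    subject_id: str
    session_index: int
    values: np.ndarray  # (27, 5), rows sum to 1

    def flatten(self) -> np.ndarray:
        return self.values.ravel()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.size != len(feature_names()):
            raise ValueError("expected a 27 x 5 relative band power matrix")
        if ((self.values < -1e-12) | (self.values > 1 + 1e-12)).any():
            raise ValueError("relative powers must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-channel band powers must sum to 1")


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def design_bandpass(taps: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Linear-phase FIR band-pass (Hamming-windowed sinc)."""
    if fs <= 2 * hi:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    return signal.firwin(taps, [lo, hi], pass_zero=False, fs=fs)


def bandpass_filter(rec: SessionRecording, taps: int = 1000, lo: float = 2.0,
                    hi: float = 45.0) -> SessionRecording:
    """Apply the band-pass per channel with linear-phase delay compensation.

    A single forward pass is used and the output is shifted by the filter's
    group delay, rounded to the nearest sample; the residual half-sample
    delay of an even-length design is irrelevant to spectral features."""
    n = rec.data.shape[1]
    if n <= taps:
        raise ValueError(f"signal length {n} must exceed filter order {taps}")
    h = design_bandpass(taps, lo, hi, rec.fs)
    delay = (taps - 1) // 2
    full = signal.oaconvolve(rec.data, h[None, :], axes=1)
    out = full[:, delay:delay + n]
    if not np.isfinite(out).all():
        raise FloatingPointError("filter produced non-finite output")
    return SessionRecording(rec.subject_id, rec.session_index, rec.channel_names,
                            rec.fs, out, rec.duration)


def demean_detrend(rec: SessionRecording) -> SessionRecording:
    """Remove the per-channel best-fit line (includes the mean)."""
    if rec.data.shape[1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    out = signal.detrend(rec.data, axis=1, type="linear")
    return SessionRecording(rec.subject_id, rec.session_index, rec.channel_names,
                            rec.fs, out, rec.duration)


def epoch_slices(n_samples: int, fs: float, window_s: float = 4.0,
                 overlap: float = 0.5) -> list[slice]:
    """Start-aligned sliding windows; with 4 s / 50% a 120 s recording yields
    floor((120-4)/2)+1 = 59 epochs."""
    win = int(round(window_s * fs))
    step = int(round(window_s * (1.0 - overlap) * fs))
    if n_samples < win:
        raise ValueError("recording shorter than one epoch window")
    count = (n_samples - win) // step + 1
    return [slice(i * step, i * step + win) for i in range(count)]


def flag_artifact_epochs(data: np.ndarray, slices: list[slice],
                         threshold_uv: float = 100.0) -> np.ndarray:
    """Boolean retain-mask over epochs: an epoch is rejected when any sample
    on any channel exceeds the amplitude threshold."""
    if threshold_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    retained = np.array(
        [not (np.abs(data[:, sl]) > threshold_uv).any() for sl in slices], dtype=bool
    )
    if not retained.any():
        raise ValueError("all epochs rejected: no usable data")
    frac = 1.0 - retained.mean()
    if frac > 0:
        logger.info("artifact rejection: %.1f%% of epochs rejected", 100 * frac)
    return retained


def drop_and_rereference(rec: SessionRecording,
                         drop: tuple[str, ...] = FRONTAL_DROP,
                         ref: str = REFERENCE) -> tuple[tuple[str, ...], np.ndarray]:
    """Remove the dropped channels, subtract the reference trace from every
    remaining channel, then remove the reference itself."""
    for name in (*drop, ref):
        if name not in rec.channel_names:
            raise ValueError(f"channel {name!r} not present in recording")
    ref_idx = rec.channel_names.index(ref)
    ref_trace = rec.data[ref_idx]
    keep = [i for i, ch in enumerate(rec.channel_names)
            if ch not in drop and ch != ref]
    names = tuple(rec.channel_names[i] for i in keep)
    data = rec.data[keep] - ref_trace
    return names, data


def relative_band_power(epoch: np.ndarray, fs: float,
                        bands: tuple[tuple[str, float, float], ...] = BANDS
                        ) -> np.ndarray | None:
    """Per-channel relative band power of one epoch.

    Hann-windowed periodogram; band power integrates the PSD over the
    half-open interval [low, high); relative power normalizes by the total
    over the full 2-45 Hz span. Returns None when an epoch has zero total
    power (flagged missing; the caller excludes it)."""
    freqs, psd = signal.periodogram(epoch, fs=fs, window="hann", axis=1)
    lo_all, hi_all = bands[0][1], bands[-1][2]
    total_mask = (freqs >= lo_all) & (freqs < hi_all)
    total = psd[:, total_mask].sum(axis=1)
    if (total <= 0).any():
        return None
    out = np.empty((epoch.shape[0], len(bands)))
    for b, (_, lo, hi) in enumerate(bands):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, b] = psd[:, mask].sum(axis=1) / total
    return out


def aggregate_median(epoch_features: list[np.ndarray]) -> np.ndarray:
    """Elementwise median over retained epochs, renormalized per channel.

    Elementwise medians do not exactly preserve the per-channel sum-to-1
    property, so rows are renormalized after the median."""
    if not epoch_features:
        raise ValueError("no retained epochs to aggregate")
    med = np.median(np.stack(epoch_features), axis=0)
    sums = med.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("degenerate epoch features: zero band-power rows")
    return med / sums


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def extract_features(rec: SessionRecording,
                     params: PreprocessParams | None = None) -> FeatureVector:
    """Run the full preprocessing chain on one session recording."""
    p = params or PreprocessParams()
    filtered = bandpass_filter(rec, p.taps, p.lo_hz, p.hi_hz)
    detrended = demean_detrend(filtered)

    # Artifact epochs are flagged on the filtered, pre-reference data
    # (minus the dropped frontal channels, which never enter the features).
    pre_keep = [i for i, ch in enumerate(detrended.channel_names)
                if ch not in p.drop_channels]
    slices = epoch_slices(detrended.data.shape[1], detrended.fs,
                          p.window_s, p.overlap)
    retained = flag_artifact_epochs(detrended.data[pre_keep], slices,
                                    p.amplitude_threshold_uv)

    names, data = drop_and_rereference(detrended, p.drop_channels, p.reference)
    feats = []
    for sl, keep in zip(slices, retained):
        if not keep:
            continue
        rbp = relative_band_power(data[:, sl], detrended.fs, p.bands)
        if rbp is not None:
            feats.append(rbp)
    values = aggregate_median(feats)
    return FeatureVector(rec.subject_id, rec.session_index, values)


def features_frame(recordings: list[SessionRecording],
                   params: PreprocessParams | None = None) -> pd.DataFrame:
    """Feature table: one row per subject-session, 135 named columns."""
    rows = []
    for rec in recordings:
        fv = extract_features(rec, params)
        row = dict(subject_id=fv.subject_id, session_index=fv.session_index)
        row.update(zip(feature_names(), fv.flatten()))
        rows.append(row)
    return pd.DataFrame(rows)


def load_edf_recording(path, subject_id: str, session_index: int) -> SessionRecording:
    """Read a single EDF file into a SessionRecording via MNE (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    return SessionRecording(subject_id, session_index, tuple(raw.ch_names),
                            raw.info["sfreq"], data,
                            data.shape[1] / raw.info["sfreq"])
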