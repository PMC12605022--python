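"""Standard resting-EEG cleaning: band-pass, bad channels, extreme-value
rejection, resampling, average reference.

The canonical chain for microstate work is

    bandpass_filter -> detect/interpolate bad channels ->
    reject_extreme_segments -> resample -> average_reference

wrapped by :func:`preprocess`. Filtering is zero-phase (Butterworth
order 4, forward-backward) so topographies are not distorted by phase
shifts. Independent-component artifact removal is deliberately a no-op
hook: synthetic recordings carry no ocular or muscle artifacts, and real
-data users can plug an external cleaner into ``ica_hook``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt, resample_poly
from fractions import Fraction

from .recording import EEGRecording, Montage

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "average_reference",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "reject_extreme_segments",
    "resample",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    band_low: float = 1.0  # Hz
    band_high: float = 30.0  # Hz
    target_sfreq: float = 250.0  # Hz
    amplitude_threshold: float = 100.0  # uV, extreme-value rejection
    reject_window: float = 1.0  # s
    bad_channel_flat_threshold: float = 0.1  # uV peak-to-peak
    bad_channel_z_threshold: float = 3.0
    interpolate_bads: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= self.target_sfreq / 2:
            raise ValueError("band_high must be below the target Nyquist")
        if self.amplitude_threshold <= 0 or self.reject_window <= 0:
            raise ValueError("rejection parameters must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def bandpass_filter(
    rec: EEGRecording, low: float, high: float, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = rec.sfreq / 2
    if high >= nyq:
        raise ValueError("upper edge must be below Nyquist")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = butter(order, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    # sosfiltfilt pads with ~3x the effective impulse response
    if rec.n_samples < 3 * (2 * order + 1):
        raise ValueError("record too short for zero-phase filtering")
    return rec.copy(data=sosfiltfilt(sos, rec.data, axis=1))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the whole-head average: per-sample mean becomes 0."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    return rec.copy(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def detect_bad_channels(
    rec: EEGRecording,
    flat_threshold: float = 0.1,
    z_threshold: float = 3.0,
) -> list[str]:
    """Flag flat channels and log-variance outliers (report only).

    A channel is bad if its peak-to-peak amplitude is below
    ``flat_threshold`` uV or the z-score of its log-variance across
    channels exceeds ``z_threshold`` in absolute value.
    """
    ptp = rec.data.max(axis=1) - rec.data.min(axis=1)
    flat = ptp < flat_threshold
    var = rec.data.var(axis=1)
    logv = np.log(np.maximum(var, 1e-30))
    sd = logv.std()
    z = np.zeros_like(logv) if sd == 0 else (logv - logv.mean()) / sd
    bad = flat | (np.abs(z) > z_threshold)
    return [rec.montage.channel_names[i] for i in np.flatnonzero(bad)]


def interpolate_bad_channels(
    rec: EEGRecording, bad: list[str], montage: Montage | None = None
) -> EEGRecording:
    """Replace bad channels by the inverse-distance-weighted mean of good ones."""
    montage = montage or rec.montage
    if not bad:
        return rec.copy()
    bad_idx = [montage.index_of(b) for b in bad]
    good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
    if len(good_idx) < 2:
        raise ValueError("need at least 2 good channels to interpolate")
    data = rec.data.copy()
    for bi in bad_idx:
        d = np.linalg.norm(
            montage.positions[good_idx] - montage.positions[bi], axis=1
        )
        w = 1.0 / np.maximum(d, 1e-9)
        w /= w.sum()
        data[bi] = w @ rec.data[good_idx]
    return rec.copy(data=data)


def reject_extreme_segments(
    rec: EEGRecording, threshold: float = 100.0, window: float = 1.0
) -> tuple[EEGRecording, np.ndarray]:
    """Drop whole windows containing any sample beyond +-threshold uV.

    The record is tiled into non-overlapping windows (a trailing partial
    window is checked too); windows where any channel exceeds the
    threshold are removed and the survivors concatenated. Returns the
    spliced recording — with the splice points recorded so that later
    microstate segments never span a cut — and a per-sample keep mask.
    Raises if nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    w = max(1, int(round(window * rec.sfreq)))
    n = rec.n_samples
    starts = np.arange(0, n, w)
    mask = np.ones(n, dtype=bool)
    for s in starts:
        stop = min(s + w, n)
        if np.any(np.abs(rec.data[:, s:stop]) > threshold):
            mask[s:stop] = False
    if not mask.any():
        raise ValueError("extreme-value rejection removed the entire record")
    kept = rec.data[:, mask]
    # splice boundaries: output positions where the input index jumps
    idx = np.flatnonzero(mask)
    jumps = np.flatnonzero(np.diff(idx) > 1) + 1
    out = EEGRecording(
        data=kept,
        sfreq=rec.sfreq,
        montage=rec.montage,
        splice_boundaries=[int(j) for j in jumps],
    )
    return out, mask


def resample(rec: EEGRecording, target_sfreq: float) -> EEGRecording:
    """Polyphase resampling to ``target_sfreq`` (downsampling only)."""
    if target_sfreq > rec.sfreq:
        raise ValueError("upsampling is not supported")
    if target_sfreq == rec.sfreq:
        return rec.copy()
    frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = target_sfreq / rec.sfreq
    boundaries = [int(round(b * ratio)) for b in rec.splice_boundaries]
    return EEGRecording(
        data=data,
        sfreq=target_sfreq,
        montage=rec.montage,
        splice_boundaries=boundaries,
    )


def preprocess(
    rec: EEGRecording,
    config: PreprocessConfig | None = None,
    ica_hook: Optional[Callable[[EEGRecording], EEGRecording]] = None,
) -> tuple[EEGRecording, dict]:
    """Full cleaning chain; returns the cleaned recording and a report.

    Order: band-pass -> bad-channel handling -> extreme-value rejection
    -> resample -> average reference. ``ica_hook`` (default: no-op) runs
    after filtering for users who attach an external artifact cleaner.
    """
    cfg = config or PreprocessConfig()
    out = bandpass_filter(rec, cfg.band_low, cfg.band_high)
    if ica_hook is not None:
        out = ica_hook(out)
    bads = detect_bad_channels(
        out, cfg.bad_channel_flat_threshold, cfg.bad_channel_z_threshold
    )
    if bads and cfg.interpolate_bads:
        out = interpolate_bad_channels(out, bads)
    out, mask = reject_extreme_segments(
        out, cfg.amplitude_threshold, cfg.reject_window
    )
    out = resample(out, cfg.target_sfreq)
    out = average_reference(out)
    report = {
        "bad_channels": bads,
        "n_samples_in": rec.n_samples,
        "n_samples_kept": int(mask.sum()),
        "dropped_fraction": float(1 - mask.mean()),
        "n_splices": len(out.splice_boundaries),
        "config": cfg.to_dict(),
    }
    return out, report
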