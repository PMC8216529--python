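"""EMG signal conditioning: zero-lag filtering, amplitude normalisation, windowing.

The chain mirrors standard surface-EMG practice for gait recordings sampled
at 1000 Hz: a zero-lag 4th-order Butterworth band-pass (nominally 10-500 Hz;
a band edge at Nyquist is not realizable, so the upper cutoff is clipped to
0.99 * fs/2 with a warning), a zero-lag mains notch at 50 Hz, amplitude
normalisation of each muscle channel by its maximal 0.5-s epoch amplitude
over the task, and segmentation into nonoverlapping 500-ms windows.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    bp_lo: float = 10.0
    bp_hi: float = 500.0
    bp_order: int = 4
    notch_hz: float = 50.0
    notch_bw: float = 2.0  # -3 dB bandwidth; Q = notch_hz / notch_bw
    norm_epoch_s: float = 0.5
    #: "epoch_rms": normalise by the max over 0.5-s epoch RMS values (robust to
    #: single-sample artifacts); "epoch_peak": by the max epoch |x| peak.
    norm_mode: str = "epoch_rms"
    window_s: float = 0.5

    def validate(self, fs: float) -> None:
        if not 0 < self.bp_lo < self.bp_hi:
            raise ValueError("require 0 < bp_lo < bp_hi")
        if self.notch_hz >= fs / 2:
            raise ValueError("notch_hz must be below Nyquist")
        n = self.window_s * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_s * fs must be an integer")
        if self.norm_mode not in ("epoch_rms", "epoch_peak"):
            raise ValueError("norm_mode must be 'epoch_rms' or 'epoch_peak'")


def _effective_bp_hi(cfg: PreprocessConfig, fs: float) -> float:
    hi = cfg.bp_hi
    if hi >= fs / 2:
        clipped = 0.99 * fs / 2
        # stacklevel=1 keeps the registry key stable so the warning is not
        # re-emitted for every recording under default filters
        warnings.warn(
            f"band-pass upper cutoff {hi} Hz is at or above Nyquist "
            f"({fs / 2} Hz); clipping to {clipped} Hz",
            UserWarning,
            stacklevel=1,
        )
        logger.debug("clipped band-pass upper cutoff %.1f -> %.1f Hz", hi, clipped)
        hi = clipped
    return hi


def bandpass_zero_lag(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero net phase shift).

    The filter is applied along the last axis, so both single channels and
    (channels, samples) matrices are accepted.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if x.shape[-1] <= 3 * cfg.bp_order:
        raise ValueError("signal too short for the requested filter order")
    hi = _effective_bp_hi(cfg, fs)
    sos = _signal.butter(
        cfg.bp_order, [cfg.bp_lo, hi], btype="bandpass", fs=fs, output="sos"
    )
    return _signal.sosfiltfilt(sos, x, axis=-1)


def notch_zero_lag(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``cfg.notch_hz``."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    x = np.asarray(x, dtype=float)
    q = cfg.notch_hz / cfg.notch_bw
    b, a = _signal.iirnotch(cfg.notch_hz, q, fs=fs)
    return _signal.filtfilt(b, a, x, axis=-1)


def epoch_amplitudes(
    x: np.ndarray, fs: float, epoch_s: float, mode: str = "epoch_rms"
) -> np.ndarray:
    """Amplitude of consecutive nonoverlapping epochs of a 1-D signal."""
    x = np.asarray(x, dtype=float)
    n_epoch = int(round(epoch_s * fs))
    n = (len(x) // n_epoch) * n_epoch
    if n == 0:
        return np.array([])
    epochs = x[:n].reshape(-1, n_epoch)
    if mode == "epoch_rms":
        return np.sqrt(np.mean(epochs**2, axis=1))
    return np.max(np.abs(epochs), axis=1)


def normalization_scale(
    signals: list[np.ndarray] | np.ndarray,
    fs: float,
    cfg: PreprocessConfig | None = None,
) -> float:
    """Maximal epoch amplitude of one channel across all trials of a task."""
    cfg = cfg or PreprocessConfig()
    if isinstance(signals, np.ndarray) and signals.ndim == 1:
        signals = [signals]
    amps = np.concatenate(
        [epoch_amplitudes(s, fs, cfg.norm_epoch_s, cfg.norm_mode) for s in signals]
    )
    if amps.size == 0:
        raise ValueError("signals shorter than one normalisation epoch")
    return float(np.max(amps))


def normalize_amplitude(
    x: np.ndarray,
    fs: float,
    cfg: PreprocessConfig | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Divide a channel by its maximal 0.5-s epoch amplitude over the task.

    ``scale`` lets the caller normalise several trials of the same
    subject x task x channel by a common, task-wide maximum; when omitted the
    maximum of ``x`` itself is used.  An all-zero channel is returned
    unchanged with a logged warning (division guard).
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if scale is None:
        scale = normalization_scale(x, fs, cfg)
    if scale == 0:
        logger.warning("all-zero channel: skipping amplitude normalisation")
        return np.zeros_like(x)
    return x / scale


def segment_windows(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Split a 1-D signal into contiguous nonoverlapping windows.

    Returns an array of shape (n_windows, window_samples); the trailing
    remainder is discarded.  A signal shorter than one window yields an empty
    (0, window_samples) array with a warning.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    x = np.asarray(x, dtype=float)
    n_win = int(round(cfg.window_s * fs))
    n_full = len(x) // n_win
    if n_full == 0:
        warnings.warn(
            f"signal of {len(x)} samples is shorter than one "
            f"{n_win}-sample window",
            UserWarning,
            stacklevel=2,
        )
    return x[: n_full * n_win].reshape(n_full, n_win)


def filter_channels(
    samples: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Band-pass then notch, per channel."""
    cfg = cfg or PreprocessConfig()
    return notch_zero_lag(bandpass_zero_lag(samples, fs, cfg), fs, cfg)


def coherence_conditioning(
    cfg: PreprocessConfig | None = None, lo: float = 1.0
) -> PreprocessConfig:
    """The conditioning used for the intermuscular-coherence path.

    Band-wise coherence is evaluated down to 1 Hz, but the amplitude-feature
    chain high-passes at 10 Hz; below that cutoff the surviving signal is so
    attenuated that Welch bins in the delta/theta bands measure spectral
    leakage from the passband instead of genuine coupling.  The coherence
    path therefore lowers the band-pass edge to the lowest analysed
    frequency while keeping the notch and normalisation identical.
    """
    cfg = cfg or PreprocessConfig()
    return dataclasses.replace(cfg, bp_lo=lo)


def preprocess_task(
    trials: list[np.ndarray], fs: float, cfg: PreprocessConfig | None = None
) -> list[np.ndarray]:
    """Full conditioning of all trials of one subject x task.

    Each trial is a (channels, samples) matrix.  All trials are filtered
    first; each channel is then normalised by its maximal epoch amplitude
    across the whole task (the filtering-before-normalisation order matters
    because filtering changes amplitudes).
    """
    cfg = cfg or PreprocessConfig()
    filtered = [filter_channels(tr, fs, cfg) for tr in trials]
    n_ch = filtered[0].shape[0]
    out = [np.empty_like(tr) for tr in filtered]
    for c in range(n_ch):
        scale = normalization_scale([tr[c] for tr in filtered], fs, cfg)
        for k, tr in enumerate(filtered):
            out[k][c] = normalize_amplitude(tr[c], fs, cfg, scale=scale)
    return out
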