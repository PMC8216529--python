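"""Spectrotemporal EMG features per 500-ms window, and the cohort feature table.

Ten classical features per window and channel. Time domain, for window
samples x_1..x_N:

    MAV = (1/N) sum |x_i|            mean absolute value
    RMS = sqrt((1/N) sum x_i^2)      root mean square
    VAR = (1/(N-1)) sum x_i^2        variance (no mean subtraction: band-passed
                                     EMG is zero-mean by construction)
    WL  = sum |x_{i+1} - x_i|        waveform length
    SSI = sum x_i^2                  simple square integral

Frequency domain, from the one-sided periodogram P_j at frequencies f_j:

    MNF = sum f_j P_j / sum P_j      mean frequency
    MDF = smallest f_j with cumulative power >= half the total (median freq.)
    PKF = f at the maximal P_j       peak frequency
    MNP = sum P_j / M                mean power
    TTP = sum P_j                    total power

These definitions imply SSI = (N-1) VAR = N RMS^2 and MNP * M = TTP exactly,
identities the test suite exploits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from musclenet import coherence as _coherence
from musclenet import preprocess as _preprocess
from musclenet.synthetic import EmgRecording

logger = logging.getLogger(__name__)

TIME_FEATURES = ("MAV", "RMS", "VAR", "WL", "SSI")
FREQ_FEATURES = ("MNF", "MDF", "PKF", "MNP", "TTP")
ALL_FEATURES = TIME_FEATURES + FREQ_FEATURES


@dataclass
class Spectrum:
    """One-sided power spectral density on a strictly increasing frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def time_features(window: np.ndarray) -> dict[str, float]:
    """MAV, RMS, VAR, WL and SSI of one window."""
    x = np.asarray(window, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("window must contain at least 2 samples (VAR undefined)")
    ssq = float(np.sum(x**2))
    return {
        "MAV": float(np.mean(np.abs(x))),
        "RMS": float(np.sqrt(ssq / n)),
        "VAR": ssq / (n - 1),
        "WL": float(np.sum(np.abs(np.diff(x)))),
        "SSI": ssq,
    }


def compute_psd(window: np.ndarray, fs: float) -> Spectrum:
    """One-sided periodogram of a window (rectangular window, no detrending).

    Satisfies Parseval: sum(P_j) * df equals the window's mean-square power.
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 8:
        raise ValueError("window too short for a PSD")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    freqs, power = _signal.periodogram(
        x, fs=fs, window="boxcar", detrend=False, scaling="density"
    )
    return Spectrum(freqs=freqs, power=power)


def freq_features(spectrum: Spectrum, pkf_literal: bool = False) -> dict[str, float]:
    """MNF, MDF, PKF, MNP and TTP of one spectrum.

    ``pkf_literal=True`` returns the maximal PSD value itself as PKF instead
    of the frequency at which it occurs (peak power rather than peak
    frequency).  Ties in the peak go to the lowest frequency.
    """
    f = spectrum.freqs
    p = spectrum.power
    total = float(np.sum(p))
    if total <= 0:
        raise ValueError("all-zero spectrum: MNF/MDF undefined")
    cum = np.cumsum(p)
    mdf = float(f[np.searchsorted(cum, total / 2.0 - 1e-12 * total)])
    peak_idx = int(np.argmax(p))  # argmax returns the first (lowest-f) maximum
    return {
        "MNF": float(np.sum(f * p) / total),
        "MDF": mdf,
        "PKF": float(p[peak_idx]) if pkf_literal else float(f[peak_idx]),
        "MNP": total / len(p),
        "TTP": total,
    }


def window_features(window: np.ndarray, fs: float) -> dict[str, float]:
    """All ten features of one window."""
    out = time_features(window)
    out.update(freq_features(compute_psd(window, fs)))
    return out


def _channel_column(feature: str, channel_label: str) -> str:
    muscle, side = channel_label.rsplit("-", 1)
    return f"{feature}_{muscle}_{side}"


def parse_feature_name(name: str) -> dict:
    """Split a column name into its (feature, muscle/pair, side) parts.

    Per-channel columns are ``<feature>_<muscle>_<side>``; coherence columns
    are ``msc_<band>_<m1>-<m2>_<side>`` and are attributed to the first-named
    muscle of the pair for muscle-level groupings.
    """
    parts = name.split("_")
    if parts[0] == "msc":
        # msc_<band>_<m1>-<m2>_<side>; band names may themselves contain "_"
        if len(parts) < 4 or "-" not in parts[-2]:
            raise ValueError(f"unparseable MSC feature name: {name}")
        m1, m2 = parts[-2].split("-")
        return {
            "feature": "MSC",
            "band": "_".join(parts[1:-2]),
            "pair": (m1, m2),
            "muscle": m1,
            "muscles": (m1, m2),
            "side": parts[-1],
        }
    if len(parts) != 3:
        raise ValueError(f"unparseable feature name: {name}")
    feat, muscle, side = parts
    return {
        "feature": feat,
        "band": None,
        "pair": None,
        "muscle": muscle,
        "muscles": (muscle,),
        "side": side,
    }


def recording_window_features(
    trials: list[np.ndarray],
    fs: float,
    channel_labels: tuple[str, ...],
    cfg: _preprocess.PreprocessConfig | None = None,
) -> dict[str, float]:
    """Window-level features of one subject x task, averaged over all windows.

    ``trials`` are preprocessed (channels, samples) matrices; windows are cut
    per trial so no window spans a trial join.
    """
    cfg = cfg or _preprocess.PreprocessConfig()
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for tr in trials:
        for c, label in enumerate(channel_labels):
            windows = _preprocess.segment_windows(tr[c], fs, cfg)
            for w in windows:
                for feat, val in window_features(w, fs).items():
                    col = _channel_column(feat, label)
                    sums[col] = sums.get(col, 0.0) + val
                    counts[col] = counts.get(col, 0) + 1
    return {col: sums[col] / counts[col] for col in sums}


def build_feature_table(
    recordings: list[EmgRecording],
    task: str,
    pre_cfg: _preprocess.PreprocessConfig | None = None,
    coh_cfg: "_coherence.CoherenceConfig | None" = None,
    preprocessed: dict[str, list[np.ndarray]] | None = None,
    coh_preprocessed: dict[str, list[np.ndarray]] | None = None,
) -> pd.DataFrame:
    """One row per subject for one task: averaged window features + MSC features.

    The index is the subject id; a ``group`` column carries the class label.
    ``preprocessed`` (subject -> list of conditioned trial matrices) can be
    supplied to reuse filtering done elsewhere; otherwise the full
    conditioning chain is applied here.  The MSC features are computed on the
    coherence conditioning (band-pass edge lowered to the lowest analysed
    band; see :func:`musclenet.preprocess.coherence_conditioning`), passed in
    as ``coh_preprocessed`` or derived here.
    """
    pre_cfg = pre_cfg or _preprocess.PreprocessConfig()
    coh_cfg = coh_cfg or _coherence.CoherenceConfig()
    by_subject: dict[str, list[EmgRecording]] = {}
    groups: dict[str, str] = {}
    labels: dict[str, tuple[str, ...]] = {}
    for rec in recordings:
        if rec.task != task:
            continue
        by_subject.setdefault(rec.subject_id, []).append(rec)
        groups[rec.subject_id] = rec.group
        labels[rec.subject_id] = rec.channel_labels
    if not by_subject:
        raise ValueError(f"no recordings for task {task!r}")
    coh_pre_cfg = _preprocess.coherence_conditioning(
        pre_cfg, lo=min(b.lo for b in coh_cfg.bands)
    )
    rows = {}
    for subject, recs in sorted(by_subject.items()):
        recs = sorted(recs, key=lambda r: r.trial_index)
        fs = recs[0].fs
        raw = [r.samples for r in recs]
        if preprocessed is not None and subject in preprocessed:
            trials = preprocessed[subject]
        else:
            trials = _preprocess.preprocess_task(raw, fs, pre_cfg)
        if coh_preprocessed is not None and subject in coh_preprocessed:
            coh_trials = coh_preprocessed[subject]
        else:
            coh_trials = _preprocess.preprocess_task(raw, fs, coh_pre_cfg)
        row = recording_window_features(trials, fs, labels[subject], pre_cfg)
        row.update(
            _coherence.coherence_features(coh_trials, fs, labels[subject], coh_cfg)
        )
        rows[subject] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.isna().any().any():  # pragma: no cover - defensive
        missing = df.columns[df.isna().any()].tolist()
        warnings.warn(f"dropping incomplete feature columns: {missing}", UserWarning)
        df = df.dropna(axis=1)
    df.insert(0, "group", [groups[s] for s in df.index])
    df.index.name = "subject"
    return df


def combine_tasks(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool per-task tables into the 'combine' view with a task indicator column."""
    frames = []
    for task, df in sorted(tables.items()):
        d = df.copy()
        d.insert(1, "task", task)
        d.index = [f"{s}|{task}" for s in d.index]
        frames.append(d)
    out = pd.concat(frames, axis=0)
    out.index.name = "sample"
    return out
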