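"""Magnitude-squared coherence between muscle pairs and band-wise features.

The estimator is the classical Welch one: auto- and cross-power spectra are
averaged over segments and combined as::

    MSC(f) = |P_xy(f)|^2 / (P_xx(f) * P_yy(f))   in [0, 1]

Averaging over at least two segments is mandatory — with a single segment the
ratio is identically 1.  With L independent segments and incoherent inputs
the estimator has a known positive bias of about 1/L, which the synthetic
cohort tests use as an oracle.

Segments are cut within each trial of a subject x task, never across a trial
join, and the per-trial spectra are pooled weighted by their segment counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal


@dataclass(frozen=True)
class BandDefinition:
    """A coherence frequency band; bins are assigned by lo < f <= hi."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs > self.lo) & (freqs <= self.hi)


#: The five bands used for connectivity: delta, theta, alpha, beta, high beta.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 25.0),
    BandDefinition("high_beta", 25.0, 30.0),
)

#: Within-side muscle pairs used as classification features.
WITHIN_SIDE_PAIRS: tuple[tuple[str, str], ...] = (
    ("SCM", "SC"),
    ("SCM", "UT"),
    ("SC", "UT"),
)


@dataclass
class CoherenceConfig:
    """Estimator settings.

    ``seg_s`` defaults to the study's 0.5-s window.  Note 0.5-s segments give
    2-Hz resolution, so the delta band (1-4 Hz) holds at most two bins; a
    longer segment (e.g. 2 s) is a documented alternative, not a silent
    change.  ``overlap_frac`` defaults to 0 (nonoverlapping windows).
    """

    seg_s: float = 0.5
    overlap_frac: float = 0.0
    window: str = "hann"
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    broadband: tuple[float, float] = (1.0, 30.0)

    def validate(self) -> None:
        if self.seg_s <= 0:
            raise ValueError("seg_s must be positive")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must be in [0, 1)")


@dataclass
class CoherenceSpectrum:
    """MSC of one channel pair on a frequency grid."""

    pair: tuple[str, str]
    freqs: np.ndarray
    msc: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.msc = np.asarray(self.msc, dtype=float)
        if self.freqs.shape != self.msc.shape:
            raise ValueError("freqs and msc must have equal length")
        if self.n_segments < 2:
            raise ValueError("MSC requires at least 2 averaged segments")
        if np.any((self.msc < -1e-12) | (self.msc > 1 + 1e-12)):
            raise ValueError("msc values must lie in [0, 1]")
        self.msc = np.clip(self.msc, 0.0, 1.0)


def _as_trials(x) -> list[np.ndarray]:
    if isinstance(x, np.ndarray) and x.ndim == 1:
        return [np.asarray(x, dtype=float)]
    return [np.asarray(tr, dtype=float) for tr in x]


def _segment_count(n: int, nperseg: int, noverlap: int) -> int:
    if n < nperseg:
        return 0
    return (n - nperseg) // (nperseg - noverlap) + 1


def msc(
    x,
    y,
    fs: float,
    cfg: CoherenceConfig | None = None,
    pair: tuple[str, str] = ("x", "y"),
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence between two signals.

    ``x`` and ``y`` may be 1-D arrays or lists of equal-length trial arrays;
    trial boundaries are respected when segmenting.
    """
    cfg = cfg or CoherenceConfig()
    cfg.validate()
    xt, yt = _as_trials(x), _as_trials(y)
    if len(xt) != len(yt) or any(len(a) != len(b) for a, b in zip(xt, yt)):
        raise ValueError("x and y must have identical trial structure and lengths")
    nperseg = int(round(cfg.seg_s * fs))
    noverlap = int(round(cfg.overlap_frac * nperseg))
    counts = [_segment_count(len(a), nperseg, noverlap) for a in xt]
    total = sum(counts)
    if total < 2:
        raise ValueError(
            "fewer than 2 segments available: a single-segment MSC is "
            "identically 1 (degenerate estimate)"
        )
    pxx = pyy = pxy = None
    freqs = None
    for a, b, cnt in zip(xt, yt, counts):
        if cnt == 0:
            continue
        kw = dict(
            fs=fs,
            window=cfg.window,
            nperseg=nperseg,
            noverlap=noverlap,
            detrend=False,
            scaling="density",
        )
        freqs, pxx_i = _signal.welch(a, **kw)
        _, pyy_i = _signal.welch(b, **kw)
        _, pxy_i = _signal.csd(a, b, **kw)
        if pxx is None:
            pxx = cnt * pxx_i
            pyy = cnt * pyy_i
            pxy = cnt * pxy_i
        else:
            pxx += cnt * pxx_i
            pyy += cnt * pyy_i
            pxy += cnt * pxy_i
    denom = pxx * pyy
    out = np.zeros_like(pxx)
    good = denom > 0
    out[good] = np.abs(pxy[good]) ** 2 / denom[good]
    return CoherenceSpectrum(pair=pair, freqs=freqs, msc=out, n_segments=total)


def band_msc(cohspec: CoherenceSpectrum, band: BandDefinition) -> float:
    """Mean MSC over the bins falling in a band (lo < f <= hi)."""
    mask = band.contains(cohspec.freqs)
    if not np.any(mask):
        raise ValueError(
            f"no frequency bins in band {band.name} ({band.lo}-{band.hi} Hz): "
            "the segment length gives a grid too coarse for this band; use a "
            "longer coherence segment (cfg.seg_s)"
        )
    return float(np.mean(cohspec.msc[mask]))


def coherence_features(
    trials: list[np.ndarray],
    fs: float,
    channel_labels: tuple[str, ...],
    cfg: CoherenceConfig | None = None,
) -> dict[str, float]:
    """Band-wise MSC features for the three within-side muscle pairs per side.

    Names follow ``msc_<band>_<m1>-<m2>_<side>``; a broadband (default
    1-30 Hz) mean per pair is emitted as ``msc_broad_<m1>-<m2>_<side>``.
    With the five default bands this yields 3 pairs x 2 sides x 6 = 36
    features.
    """
    cfg = cfg or CoherenceConfig()
    trials = _as_trials(trials) if isinstance(trials, np.ndarray) else trials
    out: dict[str, float] = {}
    broad = BandDefinition("broad", *cfg.broadband)
    for side in ("L", "R"):
        for m1, m2 in WITHIN_SIDE_PAIRS:
            c1, c2 = f"{m1}-{side}", f"{m2}-{side}"
            for c in (c1, c2):
                if c not in channel_labels:
                    raise ValueError(f"missing channel {c}")
            i1 = channel_labels.index(c1)
            i2 = channel_labels.index(c2)
            spec = msc(
                [tr[i1] for tr in trials],
                [tr[i2] for tr in trials],
                fs,
                cfg,
                pair=(c1, c2),
            )
            for band in cfg.bands:
                out[f"msc_{band.name}_{m1}-{m2}_{side}"] = band_msc(spec, band)
            out[f"msc_broad_{m1}-{m2}_{side}"] = band_msc(spec, broad)
    return out


def expected_independent_bias(n_segments: int) -> float:
    """Mean MSC of the Welch estimator for two incoherent signals (~1/L)."""
    return 1.0 / n_segments
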