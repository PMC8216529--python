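"""Synthetic gait-EMG cohorts with analytically known intermuscular coherence.

The generator emulates the statistical structure this pipeline is sensitive
to, not the biophysics of EMG: each channel is a sum of band-limited
Gaussian drives, some of which are shared between muscles, modulated by a
periodic gait envelope and corrupted by broadband measurement noise.

For a channel ``c`` the signal is::

    x_c(t) = a_c * e_c(t) * sum_b [ sqrt(g_cb) * u_b(t)
                                    + sqrt(1 - g_cb) * v_cb(t) ]
             + eps * w_c(t)

where ``u_b`` is a zero-mean, unit-variance Gaussian process band-limited to
band ``b`` and shared by every channel of the band's drive set, ``v_cb`` is
an independent band-limited noise, ``w_c`` is broadband noise, ``e_c`` a
nonnegative periodic gait envelope and ``a_c`` a per-channel amplitude.
The shared-power fraction ``g_cb`` (gamma) fixes the population
magnitude-squared coherence between two channels sharing a drive at
``g_cb * g_db`` inside the band (:func:`expected_msc`), the classical result
for two signals built from one common source plus independent noises.

Group and task effects enter exclusively through gamma and the amplitude
scale.  The default cohort plants the effects this kind of study reports:
reduced delta-band shared drive between muscles in the chronic-neck-pain
(CNP) group during curvilinear walking, and a raised sternocleidomastoid
activation amplitude in the same condition.
"""

from __future__ import annotations

import binascii
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal as _signal

CHANNELS: tuple[str, ...] = ("SCM-L", "SCM-R", "SC-L", "SC-R", "UT-L", "UT-R")
MUSCLES: tuple[str, ...] = ("SCM", "SC", "UT")
SIDES: tuple[str, ...] = ("L", "R")
GROUPS: tuple[str, ...] = ("CNP", "control")
TASKS: tuple[str, ...] = ("rectilinear", "curvilinear")

#: Per-channel gait-envelope phase offsets (radians) are small and distinct.
#: Large inter-channel offsets would decorrelate the shared drive through the
#: amplitude modulation and bias estimated coherence well below gamma_c*gamma_d.
DEFAULT_PHASE_STEP = np.pi / 30.0


class ParameterError(ValueError):
    """Raised when cohort parameters violate their invariants."""


@dataclass
class BandDrive:
    """One shared oscillatory drive: a frequency band and the channels it couples.

    ``gamma`` maps each covered channel to its baseline shared-power fraction;
    ``gamma_adjust`` maps ``"<group>:<task>"`` keys to an additive shift applied
    to every covered channel in that condition (clipped to [0, 1]).
    """

    name: str
    lo: float
    hi: float
    channels: tuple[str, ...]
    gamma: dict[str, float]
    gamma_adjust: dict[str, float] = field(default_factory=dict)

    def resolved_gamma(self, channel: str, group: str, task: str) -> float:
        g = self.gamma[channel] + self.gamma_adjust.get(f"{group}:{task}", 0.0)
        return float(np.clip(g, 0.0, 1.0))


def default_band_drives(
    delta_gamma_reduction: float = 0.25,
) -> list[BandDrive]:
    """Default drive set: one shared drive per band per side over (SCM, SC, UT).

    Baseline gammas decrease with frequency (coherence between postural
    muscles is strongest at the lowest bands); the CNP-curvilinear condition
    loses ``delta_gamma_reduction`` of shared-power fraction in delta.
    """
    baseline = {
        "delta": (1.0, 4.0, 0.5),
        "theta": (4.0, 8.0, 0.4),
        "alpha": (8.0, 12.0, 0.35),
        "beta": (12.0, 25.0, 0.3),
        "high_beta": (25.0, 30.0, 0.25),
    }
    drives = []
    for band, (lo, hi, g) in baseline.items():
        for side in SIDES:
            chans = tuple(f"{m}-{side}" for m in MUSCLES)
            adjust = {}
            if band == "delta":
                adjust["CNP:curvilinear"] = -float(delta_gamma_reduction)
            drives.append(
                BandDrive(
                    name=band,
                    lo=lo,
                    hi=hi,
                    channels=chans,
                    gamma={c: g for c in chans},
                    gamma_adjust=adjust,
                )
            )
    return drives


def default_amplitude_scale(scm_factor: float = 1.3) -> dict[str, float]:
    """CNP subjects activate SCM more strongly during curvilinear gait."""
    return {
        "CNP:curvilinear:SCM-L": float(scm_factor),
        "CNP:curvilinear:SCM-R": float(scm_factor),
    }


@dataclass
class CohortParams:
    """Design of a synthetic cohort.

    Parameters mirror the study design the pipeline targets: two groups of
    ``n_per_group`` subjects, two walking tasks, ``n_trials`` trials each,
    six neck-muscle channels sampled at ``fs`` Hz.
    """

    n_per_group: int = 20
    fs: float = 1000.0
    duration_s: float = 6.0
    n_trials: int = 3
    stride_hz: float = 1.0
    channels: tuple[str, ...] = CHANNELS
    band_drives: list[BandDrive] | None = None
    amplitude_scale: dict[str, float] | None = None
    noise_floor: float = 0.05
    seed: int = 0
    envelope_phase_step: float = DEFAULT_PHASE_STEP

    def __post_init__(self) -> None:
        if self.band_drives is None:
            self.band_drives = default_band_drives()
        if self.amplitude_scale is None:
            self.amplitude_scale = default_amplitude_scale()
        self.channels = tuple(self.channels)
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_trials < 1:
            raise ParameterError("n_per_group and n_trials must be >= 1")
        if tuple(self.channels) != CHANNELS:
            raise ParameterError(f"channel order must be {CHANNELS}")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("duration_s * fs must be an integer sample count")
        hi_max = 0.0
        for d in self.band_drives:
            if d.lo >= d.hi:
                raise ParameterError(f"band {d.name}: lo >= hi")
            if d.hi >= self.fs / 2:
                raise ParameterError(f"band {d.name}: hi >= Nyquist")
            hi_max = max(hi_max, d.hi)
            for c in d.channels:
                if c not in self.channels:
                    raise ParameterError(f"band {d.name}: unknown channel {c}")
                g = d.gamma.get(c)
                if g is None or not 0.0 <= g <= 1.0:
                    raise ParameterError(
                        f"band {d.name}: gamma for {c} must be in [0, 1]"
                    )
        if self.fs <= 2 * hi_max:
            raise ParameterError("fs must exceed twice the highest band edge")
        if self.noise_floor < 0:
            raise ParameterError("noise_floor must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def drives_covering(self, channel: str) -> list[BandDrive]:
        return [d for d in self.band_drives if channel in d.channels]

    def amplitude(self, channel: str, group: str, task: str) -> float:
        return float(self.amplitude_scale.get(f"{group}:{task}:{channel}", 1.0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        for bd in d["band_drives"]:
            bd["channels"] = list(bd["channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        d = dict(d)
        if d.get("band_drives") is not None:
            d["band_drives"] = [
                BandDrive(**{**bd, "channels": tuple(bd["channels"])})
                for bd in d["band_drives"]
            ]
        if "channels" in d and d["channels"] is not None:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass
class EmgRecording:
    """One subject x task x trial multichannel EMG signal."""

    subject_id: str
    group: str
    task: str
    trial_index: int
    fs: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray  # shape (6, N)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        if self.task not in TASKS:
            raise ParameterError(f"task must be one of {TASKS}")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ParameterError("samples must be (n_channels, N)")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


def gait_envelope(t: np.ndarray, stride_hz: float, phase: float) -> np.ndarray:
    """Nonnegative periodic activation envelope, one burst per stride."""
    s = 0.5 * (1.0 + np.sin(2.0 * np.pi * stride_hz * t + phase))
    return 0.2 + 0.8 * s**2


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz.

    White noise is zero-phase filtered with a 4th-order Butterworth band-pass;
    the in-band spectrum is flat to within the filter rolloff, which keeps the
    coherence oracle exact in the band interior.  Generous padding removes
    filter edge transients.
    """
    pad = int(min(n, max(4.0 * fs / lo, 2000)))
    white = rng.standard_normal(n + 2 * pad)
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = _signal.sosfiltfilt(sos, white)
    out = filt[pad : pad + n]
    sd = out.std()
    if sd == 0:  # pragma: no cover - cannot happen for nonempty noise
        raise ParameterError("degenerate band-limited noise")
    return out / sd


def recording_rng(
    params: CohortParams, subject_id: str, task: str, trial: int
) -> np.random.Generator:
    """Named pseudo-random stream per (subject, task, trial).

    The stream is a pure function of the cohort seed and the recording's
    identity, so cohorts are reproducible regardless of generation order.
    """
    sub_key = binascii.crc32(subject_id.encode()) & 0x7FFFFFFF
    task_key = TASKS.index(task)
    return np.random.default_rng(
        [int(params.seed) & 0x7FFFFFFF, sub_key, task_key, int(trial)]
    )


def generate_recording(
    params: CohortParams,
    subject_id: str,
    group: str,
    task: str,
    trial: int,
    rng: np.random.Generator | None = None,
) -> EmgRecording:
    """Synthesise one multichannel recording.

    Shared drives are drawn once per band drive and mixed into every covered
    channel with weights ``sqrt(gamma)`` / ``sqrt(1-gamma)``, so the
    shared-power fraction of the channel in the band equals gamma.
    """
    params.validate()
    if group not in GROUPS:
        raise ParameterError(f"group must be one of {GROUPS}")
    if task not in TASKS:
        raise ParameterError(f"task must be one of {TASKS}")
    if rng is None:
        rng = recording_rng(params, subject_id, task, trial)
    n = params.n_samples
    t = np.arange(n) / params.fs
    n_ch = len(params.channels)
    base = np.zeros((n_ch, n))
    for drive in params.band_drives:
        shared = _bandlimited_noise(rng, n, params.fs, drive.lo, drive.hi)
        for ch in drive.channels:
            g = drive.resolved_gamma(ch, group, task)
            own = _bandlimited_noise(rng, n, params.fs, drive.lo, drive.hi)
            idx = params.channels.index(ch)
            base[idx] += np.sqrt(g) * shared + np.sqrt(1.0 - g) * own

    samples = np.empty_like(base)
    for i, ch in enumerate(params.channels):
        env = gait_envelope(t, params.stride_hz, i * params.envelope_phase_step)
        env_ms = float(np.mean(env**2))
        n_cov = max(len(params.drives_covering(ch)), 1)
        amp = params.amplitude(ch, group, task)
        noise = rng.standard_normal(n)
        eps = np.sqrt(params.noise_floor * env_ms * n_cov)
        samples[i] = amp * env * base[i] + eps * noise
    return EmgRecording(
        subject_id=subject_id,
        group=group,
        task=task,
        trial_index=trial,
        fs=params.fs,
        channel_labels=params.channels,
        samples=samples,
    )


def expected_msc(
    params: CohortParams,
    pair: tuple[str, str],
    band: str,
    group: str = "control",
    task: str = "rectilinear",
) -> float:
    """Population magnitude-squared coherence for a channel pair in a band.

    For ``x = sqrt(g_c) u + noise`` and ``y = sqrt(g_d) u + noise`` with flat
    in-band spectra, the coherence inside the band is ``g_c * g_d``.  Pairs
    not coupled by any drive of the band return 0.
    """
    c, d = pair
    for drive in params.band_drives:
        if drive.name == band and c in drive.channels and d in drive.channels:
            return drive.resolved_gamma(c, group, task) * drive.resolved_gamma(
                d, group, task
            )
    return 0.0


def cohort_subjects(params: CohortParams) -> list[tuple[str, str]]:
    """Ordered (subject_id, group) pairs: CNP01.. then CTL01.."""
    subjects = [(f"CNP{i + 1:02d}", "CNP") for i in range(params.n_per_group)]
    subjects += [(f"CTL{i + 1:02d}", "control") for i in range(params.n_per_group)]
    return subjects


def generate_cohort(params: CohortParams, out_dir, overwrite: bool = False):
    """Generate the full cohort on disk and return the manifest.

    Writes one headered CSV per recording (column 1 ``time_s``, columns 2-7
    the channels in fixed order), a ``manifest.csv`` with one row per
    recording, and an echo of the parameters as ``params.yaml``.
    Regeneration with the same seed is bit-identical.
    """
    import pandas as pd

    from musclenet import io as mio

    out_dir = mio.ensure_dir(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace it"
        )
    rows = []
    for subject_id, group in cohort_subjects(params):
        for task in TASKS:
            for trial in range(1, params.n_trials + 1):
                rec = generate_recording(params, subject_id, group, task, trial)
                rel = f"recordings/{subject_id}_{task}_t{trial}.csv"
                mio.write_recording_csv(rec, out_dir / rel)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "task": task,
                        "trial": trial,
                        "fs_hz": params.fs,
                        "path": rel,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    with open(out_dir / "params.yaml", "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
    return manifest
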