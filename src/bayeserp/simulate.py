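"""Synthetic single-channel P300 oddball data.

Generates labeled EEG epochs with the statistical structure the analysis
pipeline assumes: stationary AR-colored background activity plus, for target
stimuli, a smooth positive deflection (a P300-like wave) in the poststimulus
window at a controlled signal-to-noise ratio.  A full multi-day study —
calibration day plus four testing days of block-randomized four-arrow
sessions — can be generated reproducibly from a single seed.

Sampling conventions follow the acquisition the pipeline targets: 200 Hz,
epochs of 100 prestimulus + 200 poststimulus samples (500 ms before to
1000 ms after each flash), amplitudes in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

FS_HZ = 200
N_PRE = 100
N_POST = 200
DIRECTIONS = ("up", "right", "down", "left")

__all__ = [
    "FS_HZ",
    "N_PRE",
    "N_POST",
    "DIRECTIONS",
    "ERPTemplate",
    "NoiseSpec",
    "RawEpoch",
    "SessionData",
    "SubjectData",
    "Study",
    "make_erp_template",
    "sample_ar_noise",
    "make_epoch",
    "make_recording",
    "generate_study",
    "epochs_to_array",
    "DEFAULT_AR_COEFFS",
    "DEFAULT_NOISE",
]


@dataclass(frozen=True)
class ERPTemplate:
    """Noise-free target waveform over the poststimulus window."""

    waveform: np.ndarray
    peak_latency_ms: float
    peak_amplitude: float
    fwhm_ms: float
    fs_hz: float = FS_HZ


@dataclass(frozen=True)
class NoiseSpec:
    """Background-EEG model: stable AR process plus optional slow drift.

    ``ar_coeffs`` are (a1..ap) in the convention x[t] = sum a_k x[t-k] + e[t];
    ``innovation_var`` is the variance of e (µV²); ``drift_amplitude`` (µV)
    scales a slow sinusoidal baseline wander added on top of the AR process.
    """

    ar_coeffs: tuple
    innovation_var: float
    drift_amplitude: float = 0.0

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.ar_coeffs, dtype=float))
        if a.size and np.any(np.abs(np.roots(np.r_[1.0, -a])) >= 1.0):
            raise ValueError("AR coefficients are not stable")
        if self.innovation_var < 0:
            raise ValueError("innovation_var must be >= 0")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be >= 0")
        object.__setattr__(self, "ar_coeffs", tuple(float(c) for c in a))


@dataclass(frozen=True)
class RawEpoch:
    """One 300-sample single-channel sweep around a stimulus."""

    pre: np.ndarray
    post: np.ndarray
    label: str
    subject_id: str = ""
    day: str = ""
    session: int = 0
    fs_hz: float = FS_HZ

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.shape != (N_PRE,) or post.shape != (N_POST,):
            raise ValueError(
                f"epoch must have {N_PRE} pre and {N_POST} post samples, "
                f"got {pre.shape} / {post.shape}"
            )
        if self.label not in ("target", "nontarget"):
            raise ValueError(f"unknown label {self.label!r}")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)


@dataclass
class SessionData:
    """Epochs of one BCI session plus the flash sequence that produced them."""

    day: str
    index: int
    desired_direction: str
    flashed_directions: list
    epochs: list


@dataclass
class SubjectData:
    subject_id: str
    template: ERPTemplate
    noise: NoiseSpec
    snr_db: float
    sessions: list = field(default_factory=list)

    def sessions_for(self, days) -> list:
        days = (days,) if isinstance(days, str) else tuple(days)
        return [s for s in self.sessions if s.day in days]


@dataclass
class Study:
    subjects: list
    seed: int | None = None


# Fixed default background process: AR(4) with a ~10 Hz (alpha-like) spectral
# peak and two real low-pass poles giving a 1/f-like roll-off, as in
# band-limited resting EEG.  The innovation variance is set so the stationary
# process RMS is ~12 µV, a typical scalp-EEG amplitude.
_POLES = np.array(
    [0.88 * np.exp(1j * 2 * np.pi * 10 / FS_HZ),
     0.88 * np.exp(-1j * 2 * np.pi * 10 / FS_HZ),
     0.6, 0.5]
)
DEFAULT_AR_COEFFS = tuple((-np.poly(_POLES).real[1:]).tolist())
DEFAULT_NOISE = NoiseSpec(ar_coeffs=DEFAULT_AR_COEFFS, innovation_var=0.37)


def make_erp_template(
    peak_latency_ms: float,
    peak_amplitude: float = 10.0,
    fwhm_ms: float = 250.0,
    n_post: int = N_POST,
    fs_hz: float = FS_HZ,
) -> ERPTemplate:
    """Gaussian-bump ERP template, truncated to zero outside ±3 FWHM."""
    window_ms = n_post / fs_hz * 1000.0
    if not 0.0 < peak_latency_ms < window_ms:
        raise ValueError(
            f"peak_latency_ms must lie in (0, {window_ms}), got {peak_latency_ms}"
        )
    t_ms = np.arange(n_post) / fs_hz * 1000.0
    sigma_ms = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = peak_amplitude * np.exp(-0.5 * ((t_ms - peak_latency_ms) / sigma_ms) ** 2)
    w[np.abs(t_ms - peak_latency_ms) > 3.0 * fwhm_ms] = 0.0
    return ERPTemplate(
        waveform=w,
        peak_latency_ms=float(peak_latency_ms),
        peak_amplitude=float(peak_amplitude),
        fwhm_ms=float(fwhm_ms),
        fs_hz=float(fs_hz),
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_ar_noise(noise: NoiseSpec, n: int, seed=None, burn_in: int | None = None) -> np.ndarray:
    """Draw a length-``n`` realization of the AR background process.

    A burn-in of ``10 * max(p, 50)`` samples (configurable) is simulated and
    discarded so the returned segment is effectively stationary.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(seed)
    a = np.asarray(noise.ar_coeffs, dtype=float)
    if burn_in is None:
        burn_in = 10 * max(a.size, 50)
    if noise.innovation_var == 0.0:
        return np.zeros(n)
    e = rng.normal(0.0, np.sqrt(noise.innovation_var), size=burn_in + n)
    x = lfilter([1.0], np.r_[1.0, -a], e)
    return x[burn_in:]


def _drift(noise: NoiseSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if noise.drift_amplitude == 0.0:
        return np.zeros(n)
    f = rng.uniform(0.05, 0.3)  # Hz, below the ERP band
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / FS_HZ
    return noise.drift_amplitude * np.sin(2.0 * np.pi * f * t + phase)


def make_epoch(
    template: ERPTemplate,
    noise_spec: NoiseSpec,
    label: str,
    snr_db: float,
    seed=None,
    subject_id: str = "",
    day: str = "",
    session: int = 0,
    return_parts: bool = False,
):
    """Build one epoch: prestimulus noise, poststimulus noise (+ scaled ERP).

    For target epochs the template is rescaled so that the realized
    poststimulus power ratio ``10*log10(P_signal / P_noise)`` equals
    ``snr_db`` exactly.  ``snr_db=+inf`` yields a noise-free poststimulus
    window equal to the template.  Nontarget epochs never contain the
    template.  With ``return_parts=True`` the scaled signal and the noise
    component of the poststimulus window are returned alongside the epoch.
    """
    rng = _as_rng(seed)
    sweep = sample_ar_noise(noise_spec, N_PRE + N_POST, rng)
    sweep = sweep + _drift(noise_spec, N_PRE + N_POST, rng)
    pre = sweep[:N_PRE]
    post_noise = sweep[N_PRE:].copy()
    signal = np.zeros(N_POST)
    if label == "target":
        w = template.waveform
        p_sig = float(np.mean(w**2))
        p_noise = float(np.mean(post_noise**2))
        if np.isinf(snr_db) and snr_db > 0:
            signal = w.copy()
            post_noise = np.zeros(N_POST)
        elif p_sig > 0.0 and p_noise > 0.0:
            scale = np.sqrt(p_noise * 10.0 ** (snr_db / 10.0) / p_sig)
            signal = scale * w
    post = post_noise + signal
    epoch = RawEpoch(
        pre=pre, post=post, label=label,
        subject_id=subject_id, day=day, session=session,
    )
    if return_parts:
        return epoch, signal, post_noise
    return epoch


def make_recording(
    template: ERPTemplate,
    noise_spec: NoiseSpec,
    directions,
    desired_direction: str,
    snr_db: float,
    seed=None,
    isi_s: float = 2.5,
):
    """Render a session as one continuous recording with stimulus markers.

    Flashes are ``isi_s`` apart; each target flash adds the SNR-scaled
    template to the 200 samples after its onset (scaling uses the noise power
    of that window so per-epoch SNR matches :func:`make_epoch`).  Returns a
    :class:`bayeserp.epoching.ContinuousRecording`.
    """
    from .epoching import ContinuousRecording  # local import: avoid cycle

    rng = _as_rng(seed)
    step = int(round(isi_s * FS_HZ))
    n = N_PRE + step * (len(directions) - 1) + N_POST
    samples = sample_ar_noise(noise_spec, n, rng) + _drift(noise_spec, n, rng)
    onsets = N_PRE + step * np.arange(len(directions))
    labels = ["target" if d == desired_direction else "nontarget" for d in directions]
    w = template.waveform
    p_sig = float(np.mean(w**2))
    for onset, lab in zip(onsets, labels):
        if lab != "target" or p_sig == 0.0:
            continue
        seg = samples[onset : onset + N_POST]
        p_noise = float(np.mean(seg**2))
        if np.isinf(snr_db) and snr_db > 0:
            samples[onset : onset + N_POST] = w
        elif p_noise > 0.0:
            samples[onset : onset + N_POST] = seg + np.sqrt(
                p_noise * 10.0 ** (snr_db / 10.0) / p_sig
            ) * w
    return ContinuousRecording(
        samples=samples,
        fs_hz=FS_HZ,
        stimulus_onsets=onsets.tolist(),
        stimulus_labels=labels,
    )


def _session_flashes(rng: np.random.Generator, n_blocks: int = 4):
    """Flash sequence of one session: randomized 4-arrow blocks, the last
    block truncated right after its target flash (so 4 blocks give 13–16
    flashes, depending on where the target lands in the final block)."""
    desired = DIRECTIONS[rng.integers(4)]
    flashes = []
    for b in range(n_blocks):
        block = [DIRECTIONS[i] for i in rng.permutation(4)]
        if b == n_blocks - 1:
            block = block[: block.index(desired) + 1]
        flashes.extend(block)
    return desired, flashes


def generate_study(
    n_subjects: int = 1,
    sessions_per_day: int = 4,
    snr_db_range=(0.0, 6.0),
    seed=None,
    n_calibration_sessions: int = 8,
    n_testing_days: int = 4,
    noise_spec: NoiseSpec | None = None,
    latency_jitter_ms: float = 30.0,
    amplitude_jitter: float = 0.15,
) -> Study:
    """Generate a reproducible multi-day study.

    Each subject gets a fixed ERP template (Gaussian bump, latency jittered
    around 450 ms, FWHM around 250 ms), a fixed noise spec, and an SNR drawn
    uniformly from ``snr_db_range``; then 8 calibration sessions followed by
    ``n_testing_days`` days of ``sessions_per_day`` sessions each.  Every
    session is block-randomized with exactly one target flash per block.
    """
    rng = _as_rng(seed)
    base_noise = noise_spec if noise_spec is not None else DEFAULT_NOISE
    subjects = []
    for i in range(n_subjects):
        latency = float(np.clip(rng.normal(450.0, latency_jitter_ms), 250.0, 700.0))
        fwhm = float(np.clip(rng.normal(250.0, 20.0), 150.0, 350.0))
        amp = 10.0 * float(np.exp(rng.normal(0.0, amplitude_jitter)))
        template = make_erp_template(latency, amp, fwhm)
        lo, hi = snr_db_range
        snr_db = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        subject = SubjectData(
            subject_id=f"S{i + 1:02d}", template=template,
            noise=base_noise, snr_db=snr_db,
        )
        day_plan = [("calibration", n_calibration_sessions)] + [
            (f"T{d + 1}", sessions_per_day) for d in range(n_testing_days)
        ]
        for day, n_sessions in day_plan:
            for s in range(n_sessions):
                desired, flashes = _session_flashes(rng)
                epochs = []
                for direction in flashes:
                    label = "target" if direction == desired else "nontarget"
                    epochs.append(
                        make_epoch(
                            template, base_noise, label, snr_db, rng,
                            subject_id=subject.subject_id, day=day, session=s,
                        )
                    )
                subject.sessions.append(
                    SessionData(
                        day=day, index=s, desired_direction=desired,
                        flashed_directions=list(flashes), epochs=epochs,
                    )
                )
        subjects.append(subject)
    return Study(subjects=subjects, seed=None if seed is None else int(seed))


def epochs_to_array(epochs) -> tuple[np.ndarray, np.ndarray]:
    """Stack epochs into an (n, 300) array of pre+post samples and a label array."""
    X = np.stack([np.concatenate([e.pre, e.post]) for e in epochs])
    y = np.array([e.label for e in epochs])
    return X, y
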