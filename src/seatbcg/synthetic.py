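"""Synthetic plant for the seat-mounted heartbeat monitor.

Generates 16 x 16 backrest pressure recordings with an embedded cardiac
component, paired ECG-like reference traces, and labelled posture-frame
datasets.  The simulator emulates the statistical structure the downstream
pipeline assumes:

* six driving postures with distinct static pressure distributions — four
  regular postures differing in contact height and spread, plus a 10-degree
  left lean (posture 5) and right lean (posture 6);
* an additive heartbeat component whose local amplitude is proportional to
  the static contact pressure (ballistocardiographic coupling through the
  back), so the power-spectrum peak map mirrors the mean-pressure map;
* lean postures couple the heartbeat far more weakly — the trunk rests on
  the seat bolster rather than flat on the mat — which is what makes the
  cardiac signal non-extractable there;
* i.i.d. Gaussian sensor noise.

Defaults correspond to the study conditions: 60 s recordings at 30 Hz, heart
rate in the mid-to-high 70s bpm, and a 10 subjects x 20 groups x 6 postures
classification dataset (1200 frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import GRID_SIZE, N_SENSORS, PressureRecording

__all__ = [
    "PostureTemplate",
    "SimulationConfig",
    "SyntheticTruth",
    "posture_template",
    "heartbeat_waveform",
    "synth_ecg",
    "generate_recording",
    "generate_posture_dataset",
]

POSTURE_IDS = (1, 2, 3, 4, 5, 6)

#: pressure (V) above which a mat cell counts as back contact
CONTACT_THRESHOLD_V = 0.4
#: heartbeat coupling gain: volts of cardiac oscillation per volt of static load
COUPLING_PER_VOLT = 0.05
#: residual coupling fraction at the 10-degree lean postures (5 and 6); the
#: trunk rolls onto the seat bolster and barely loads the mat cardiac-wise
LEAN_ATTENUATION = 0.003
#: cardiac coupling is strongest directly behind the heart: width (cells) and
#: floor of the localised emphasis multiplying the pressure-proportional trend
HEART_SPOT_SIGMA = 0.75
HEART_SPOT_FLOOR = 0.3

# Template geometry per posture: centre row/col of the contact patch, row/col
# Gaussian spreads, peak static pressure (V), patch rotation (deg) and a
# lateral loading skew (fractional pressure gradient across the patch).
# Postures 1-4 differ in contact height and spread (postural-angle changes);
# 5 and 6 are posture 1 leaned 10 degrees left/right: the contact mass moves
# ~3 columns sideways and the loading becomes asymmetric.
_POSTURE_GEOMETRY: dict[int, dict[str, float]] = {
    1: dict(row=7.1, col=7.9, sig_r=3.2, sig_c=2.6, peak=2.6, rot=0.0, skew=0.0),
    2: dict(row=9.1, col=7.1, sig_r=2.6, sig_c=2.4, peak=2.8, rot=0.0, skew=0.0),
    3: dict(row=5.9, col=8.1, sig_r=3.8, sig_c=2.9, peak=2.3, rot=0.0, skew=0.0),
    4: dict(row=8.9, col=8.9, sig_r=4.4, sig_c=3.4, peak=2.45, rot=0.0, skew=0.0),
    5: dict(row=7.1, col=4.9, sig_r=3.4, sig_c=2.1, peak=2.7, rot=10.0, skew=-0.35),
    6: dict(row=7.1, col=10.1, sig_r=3.0, sig_c=2.9, peak=2.4, rot=-10.0, skew=0.25),
}


@dataclass(frozen=True)
class PostureTemplate:
    """Deterministic static description of one driving posture on the mat."""

    posture_id: int
    base_map: np.ndarray      # 16x16 mean static pressure, volts
    contact_mask: np.ndarray  # 16x16 bool, cells the back actually presses
    coupling_map: np.ndarray  # 16x16 heartbeat gain, volts per unit waveform

    @property
    def best_sensor(self) -> int:
        """1-based index of the maximum-coupling sensor."""
        return int(np.argmax(self.coupling_map)) + 1

    def column_centroid(self) -> float:
        """Pressure-weighted column centre of the contact mass."""
        cols = np.arange(GRID_SIZE)[None, :] * np.ones((GRID_SIZE, 1))
        w = self.base_map * self.contact_mask
        return float((w * cols).sum() / w.sum())


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording."""

    posture_id: int = 1
    duration: float = 60.0        # s
    sample_rate: float = 30.0     # Hz
    heart_rate: float = 77.0      # bpm
    coupling_scale: float = 1.0   # multiplier on the template coupling map
    noise_sd: float = 0.005       # V, additive white sensor noise
    subject_scale: float = 1.0    # body-weight multiplier on static load
    waveform: str = "sine"        # mechanical heartbeat shape: "sine" | "pulse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.posture_id not in POSTURE_IDS:
            raise ValueError(f"posture_id must be one of {POSTURE_IDS}, got {self.posture_id}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.sample_rate <= 2.0 * self.heart_rate / 60.0:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz violates Nyquist for "
                f"heart_rate {self.heart_rate} bpm"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.coupling_scale < 0 or self.subject_scale <= 0:
            raise ValueError("coupling_scale must be >= 0 and subject_scale > 0")
        if self.waveform not in ("sine", "pulse"):
            raise ValueError(f"waveform must be 'sine' or 'pulse', got {self.waveform!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth bundled with a synthetic recording, for testing."""

    heartbeat_waveform: np.ndarray  # unit-amplitude embedded cardiac series
    ecg_reference: np.ndarray       # paired ECG-like trace on the same time base
    true_best_sensor: int           # 1-based index of the max-coupling sensor
    config: SimulationConfig


def posture_template(posture_id: int) -> PostureTemplate:
    """Build the deterministic pressure/coupling template for one posture.

    The static load is a rotated anisotropic Gaussian patch with an optional
    lateral skew; the contact mask collects cells above
    ``CONTACT_THRESHOLD_V``; the coupling map follows the static pressure
    modulated by a localised emphasis behind the heart (and is attenuated by
    ``LEAN_ATTENUATION`` for the lean postures 5 and 6).
    """
    if posture_id not in POSTURE_IDS:
        raise ValueError(f"posture_id must be one of {POSTURE_IDS}, got {posture_id}")
    g = _POSTURE_GEOMETRY[posture_id]
    rows, cols = np.mgrid[0:GRID_SIZE, 0:GRID_SIZE].astype(float)
    dr, dc = rows - g["row"], cols - g["col"]
    th = np.deg2rad(g["rot"])
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    base = g["peak"] * np.exp(-(u**2 / (2 * g["sig_r"] ** 2) + v**2 / (2 * g["sig_c"] ** 2)))
    base *= np.clip(1.0 + g["skew"] * dc / GRID_SIZE, 0.2, None)
    mask = base >= CONTACT_THRESHOLD_V
    gain = COUPLING_PER_VOLT * (LEAN_ATTENUATION if posture_id in (5, 6) else 1.0)
    # localised cardiac emphasis centred on the contact peak, on top of the
    # pressure-proportional trend: gives a unique, clearly dominant optimum
    # sensor while keeping the peak map concordant with the pressure map
    spot = np.exp(-(dr**2 + dc**2) / (2 * HEART_SPOT_SIGMA**2))
    coupling = np.where(mask, gain * base * (HEART_SPOT_FLOOR + (1 - HEART_SPOT_FLOOR) * spot), 0.0)
    return PostureTemplate(posture_id, base, mask, coupling)


def heartbeat_waveform(t: np.ndarray, heart_rate: float, kind: str = "sine") -> np.ndarray:
    """Unit-amplitude periodic cardiac displacement waveform.

    Parameters
    ----------
    t
        Sample times, seconds.
    heart_rate
        Beats per minute; the waveform period is ``60 / heart_rate`` s.
    kind
        ``"sine"`` for a pure tone at the beat frequency, ``"pulse"`` for a
        train of Gaussian bumps (one per beat, width 8% of the cycle).
    """
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    t = np.asarray(t, dtype=float)
    f = heart_rate / 60.0
    if kind == "sine":
        return np.sin(2.0 * np.pi * f * t)
    if kind == "pulse":
        phase = (t * f) % 1.0
        d = np.minimum(np.abs(phase - 0.5), 1.0 - np.abs(phase - 0.5))
        return np.exp(-(d**2) / (2 * 0.08**2))
    raise ValueError(f"kind must be 'sine' or 'pulse', got {kind!r}")


def synth_ecg(
    duration: float,
    sample_rate: float,
    heart_rate: float,
    seed,
    noise_sd: float = 0.002,
) -> np.ndarray:
    """ECG-like reference trace: one R-like spike per beat plus weak noise.

    Only the periodicity and phase of the trace matter downstream (the
    correlation stage band-filters it anyway), so the spike train carries no
    PQST morphology.  Phase-locked to :func:`heartbeat_waveform` for the same
    heart rate: beats fall at ``k / f`` seconds.
    """
    if duration <= 0 or sample_rate <= 0 or heart_rate <= 0:
        raise ValueError("duration, sample_rate and heart_rate must be positive")
    if sample_rate <= 2.0 * heart_rate / 60.0:
        raise ValueError("sample_rate violates Nyquist for the given heart_rate")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    f = heart_rate / 60.0
    beat_times = np.arange(0.0, duration + 1.0 / f, 1.0 / f)
    amps = 1.0 + 0.02 * rng.standard_normal(beat_times.size)
    sigma = 0.04  # s, R-spike width
    ecg = np.zeros(n)
    for tk, a in zip(beat_times, amps):
        lo = max(0, int((tk - 5 * sigma) * sample_rate))
        hi = min(n, int((tk + 5 * sigma) * sample_rate) + 1)
        ecg[lo:hi] += a * np.exp(-((t[lo:hi] - tk) ** 2) / (2 * sigma**2))
    ecg += noise_sd * rng.standard_normal(n)
    return ecg


def count_r_peaks(ecg: np.ndarray, min_height: float = 0.5) -> int:
    """Count R-like spikes in a synthetic ECG trace (test/QC helper)."""
    peaks, _ = find_peaks(np.asarray(ecg, dtype=float), height=min_height)
    return int(peaks.size)


def generate_recording(config: SimulationConfig) -> tuple[PressureRecording, SyntheticTruth]:
    """Simulate one pressure-mat recording plus its ground truth.

    Each sensor reads::

        base_map * subject_scale
        + coupling_scale * coupling_map * heartbeat_waveform(t)
        + N(0, noise_sd)

    sampled at ``sample_rate`` for ``duration`` seconds.  Identical configs
    (including seed) give bit-identical output.
    """
    tpl = posture_template(config.posture_id)
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    w = heartbeat_waveform(t, config.heart_rate, config.waveform)
    base = (tpl.base_map * config.subject_scale).ravel()
    coupling = (config.coupling_scale * tpl.coupling_map).ravel()

    rng = np.random.default_rng(config.seed)
    samples = base[None, :] + np.outer(w, coupling)
    if config.noise_sd > 0:
        samples = samples + config.noise_sd * rng.standard_normal((n, N_SENSORS))
    ecg = synth_ecg(
        config.duration, config.sample_rate, config.heart_rate, seed=[config.seed, 0x5EA7]
    )
    truth = SyntheticTruth(
        heartbeat_waveform=w,
        ecg_reference=ecg,
        true_best_sensor=int(np.argmax(coupling)) + 1,
        config=config,
    )
    return PressureRecording(samples, config.sample_rate), truth


def generate_posture_dataset(
    n_subjects: int = 10,
    n_groups_per_posture: int = 20,
    postures: tuple[int, ...] = POSTURE_IDS,
    seed: int = 0,
    frame_noise_sd: float = 0.02,
    jitter_sd: float = 0.03,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled posture-frame dataset for classifier training.

    For every subject x posture x group one static frame is drawn from the
    posture template with a per-subject body-weight scale (uniform in
    [0.85, 1.15], matching a realistic adult weight span), a per-frame
    multiplicative jitter of ``jitter_sd`` and additive sensor noise of
    ``frame_noise_sd`` volts.  The defaults reproduce the study's
    10 x 20 x 6 = 1200-frame design.

    Returns
    -------
    frames : (K, 16, 16) float array
    labels : (K,) int array of posture ids
    """
    if n_subjects < 1 or n_groups_per_posture < 1:
        raise ValueError("counts must be >= 1")
    postures = tuple(postures)
    if not postures:
        raise ValueError("postures must be non-empty")
    for p in postures:
        if p not in POSTURE_IDS:
            raise ValueError(f"invalid posture id {p}")

    rng = np.random.default_rng(seed)
    templates = {p: posture_template(p) for p in postures}
    frames, labels = [], []
    for _ in range(n_subjects):
        subject_scale = rng.uniform(0.85, 1.15)
        for p in postures:
            base = templates[p].base_map
            for _ in range(n_groups_per_posture):
                jitter = 1.0 + jitter_sd * rng.standard_normal()
                frame = subject_scale * jitter * base
                frame = frame + frame_noise_sd * rng.standard_normal(base.shape)
                frames.append(np.clip(frame, 0.0, None))
                labels.append(p)
    return np.asarray(frames), np.asarray(labels, dtype=int)
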