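"""Synthetic EEG sessions and feature streams.

The authentication method was designed around visual-oddball EEG sessions
(45 subjects, 150 trials of which 60 are target stimuli, five
occipito-temporal channels at 512 Hz) recorded under three ambient-noise
conditions. No such dataset ships with this package, so this module
generates signals with the statistical structure the method relies on:

* subject-specific alpha peak frequency and band powers,
* stimulus-locked alpha phase on target trials (von Mises concentration),
* condition-dependent beta amplitude and noise floor,
* pairwise channel coupling via linear mixing,
* occasional >100 uV artefact trials,
* slow multiplicative drift of band powers across the stream.

A direct feature-space generator (:func:`simulate_feature_stream`) skips
signal synthesis: per-subject multivariate-normal feature clouds with
linear mean drift, one client subject against 44 impostors (the 1:44 object
imbalance of a 45-subject pool).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .descriptor import DEFAULT_CHANNELS, EEGRecording

__all__ = [
    "Condition",
    "SubjectParams",
    "SimulatedSession",
    "sample_subject",
    "simulate_session",
    "simulate_feature_stream",
]


class Condition(str, Enum):
    QUIET = "quiet"
    LOW_DISTRACTION = "low_distraction"
    HIGH_DISTRACTION = "high_distraction"


# beta amplitude multiplier and extra noise floor (uV) per ambient condition
_CONDITION_EFFECTS = {
    Condition.QUIET: (1.0, 0.0),
    Condition.LOW_DISTRACTION: (1.4, 1.0),
    Condition.HIGH_DISTRACTION: (1.8, 2.0),
}


@dataclass(frozen=True)
class SubjectParams:
    alpha_peak_hz: float
    alpha_power: float
    beta_power: float
    phase_lock_kappa: float
    coupling: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]
    artifact_rate: float
    drift_rate: float


@dataclass(frozen=True)
class SimulatedSession:
    recording: EEGRecording
    trial_labels: tuple[str, ...]  # "target" / "nontarget"
    condition: Condition
    subject_id: int
    seed: int


def sample_subject(seed: int, n_channels: int = 5) -> SubjectParams:
    """Draw one subject's parameters from documented distributions."""
    rng = np.random.default_rng(seed)
    alpha_peak = float(rng.uniform(8.0, 13.0))
    alpha_power = float(rng.lognormal(mean=np.log(8.0), sigma=0.4))
    beta_power = float(rng.lognormal(mean=np.log(3.0), sigma=0.4))
    kappa = float(rng.gamma(shape=2.0, scale=2.0))
    # symmetric coupling from a random template, unit diagonal
    raw = rng.uniform(0.2, 0.8, size=(n_channels, n_channels))
    coupling = 0.5 * (raw + raw.T)
    np.fill_diagonal(coupling, 1.0)
    artifact_rate = float(rng.uniform(0.01, 0.06))
    drift_rate = float(rng.uniform(0.0, 0.002))
    return SubjectParams(
        alpha_peak_hz=alpha_peak,
        alpha_power=alpha_power,
        beta_power=beta_power,
        phase_lock_kappa=kappa,
        coupling=coupling,
        artifact_rate=artifact_rate,
        drift_rate=drift_rate,
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def simulate_session(
    params: SubjectParams,
    condition: Condition = Condition.QUIET,
    n_trials: int = 150,
    n_target: int = 60,
    seed: int = 0,
    fs: float = 512.0,
    trial_len_s: float = 2.5,
) -> SimulatedSession:
    """One session: ``n_trials`` shuffled trials (60 target / 90 non-target
    by default) of 2.5 s each, onsets at the start of every trial."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    condition = Condition(condition)
    rng = np.random.default_rng(seed)
    n_ch = params.coupling.shape[0]
    n_samp = int(round(trial_len_s * fs))
    beta_gain, noise_floor = _CONDITION_EFFECTS[condition]

    labels = np.array(
        ["target"] * min(n_target, n_trials)
        + ["nontarget"] * max(n_trials - n_target, 0)
    )
    rng.shuffle(labels)

    t = np.arange(n_samp) / fs
    trials = np.empty((n_trials, n_ch, n_samp))
    alpha_scale = 1.0
    for m in range(n_trials):
        # independent sources per channel, then linear mixing by coupling
        src = np.empty((n_ch, n_samp))
        for c in range(n_ch):
            if labels[m] == "target" and params.phase_lock_kappa > 0:
                phase = rng.vonmises(0.0, params.phase_lock_kappa)
            else:
                phase = rng.uniform(-np.pi, np.pi)
            alpha = (
                np.sqrt(params.alpha_power * alpha_scale)
                * np.cos(2 * np.pi * params.alpha_peak_hz * t + phase)
            )
            beta_f = rng.uniform(15.0, 25.0)
            beta = (
                np.sqrt(params.beta_power) * beta_gain
                * np.cos(2 * np.pi * beta_f * t + rng.uniform(-np.pi, np.pi))
            )
            noise = (2.0 + noise_floor) * _pink_noise(rng, n_samp)
            src[c] = alpha + beta + noise
        mixed = params.coupling @ src
        # renormalise rows so coupling changes correlation, not power
        mixed /= np.linalg.norm(params.coupling, axis=1)[:, None]
        if rng.random() < params.artifact_rate:
            # transient movement artefact well above the 100 uV screen
            c = rng.integers(n_ch)
            centre = rng.integers(n_samp)
            width = int(0.1 * fs)
            lo, hi = max(0, centre - width), min(n_samp, centre + width)
            mixed[c, lo:hi] += 150.0 * np.hanning(hi - lo)
        trials[m] = mixed
        alpha_scale *= 1.0 + params.drift_rate

    samples = trials.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp)
    onsets = np.arange(n_trials) * n_samp
    names = tuple(DEFAULT_CHANNELS[:n_ch]) if n_ch <= 5 else tuple(
        f"CH{i}" for i in range(n_ch)
    )
    rec = EEGRecording(samples, fs=fs, channel_names=names, onsets=onsets)
    return SimulatedSession(
        recording=rec,
        trial_labels=tuple(labels.tolist()),
        condition=condition,
        subject_id=-1,
        seed=seed,
    )


def simulate_feature_stream(
    n_subjects: int = 45,
    n_per_subject: int = 150,
    client_subject: int = 0,
    n_features: int = 12,
    drift: float = 1.0,
    between_scale: float = 1.0,
    within_scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-space stream: per-subject Gaussian clouds with mean drift.

    Subject means are drawn from N(0, between_scale^2 I); objects from
    N(mean_t, within_scale^2 Sigma_s) with a random subject covariance of
    unit average scale. Each subject's mean translates by ``drift`` (in
    within-scale units) along a random direction over the course of the
    stream. Objects of ``client_subject`` are labelled ``client``, all
    others ``impostor``; arrival order is a seeded global shuffle. Defaults
    give 6750 objects at a 150:6600 (1:44) client:impostor imbalance.
    """
    if not (0 <= client_subject < n_subjects):
        raise ValueError("client_subject out of range")
    rng = np.random.default_rng(seed)
    total = n_subjects * n_per_subject

    means = rng.normal(0.0, between_scale, size=(n_subjects, n_features))
    drift_dirs = rng.standard_normal((n_subjects, n_features))
    drift_dirs /= np.linalg.norm(drift_dirs, axis=1, keepdims=True)
    # per-subject covariance: random orientation, unit average variance
    covs = []
    for _ in range(n_subjects):
        A = rng.standard_normal((n_features, n_features)) / np.sqrt(n_features)
        cov = A @ A.T + 0.5 * np.eye(n_features)
        cov *= n_features / np.trace(cov)
        covs.append(within_scale**2 * cov)

    # arrival order: seeded global shuffle of (subject, trial) pairs
    order = np.repeat(np.arange(n_subjects), n_per_subject)
    rng.shuffle(order)
    progress = np.linspace(0.0, 1.0, total)

    X = np.empty((total, n_features))
    labels = []
    for pos in range(total):
        s = order[pos]
        mean = means[s] + drift * within_scale * progress[pos] * drift_dirs[s]
        X[pos] = rng.multivariate_normal(mean, covs[s], method="cholesky")
        labels.append("client" if s == client_subject else "impostor")

    table = pd.DataFrame(X, columns=[f"feat_{j:02d}" for j in range(n_features)])
    table["class"] = labels
    return table
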