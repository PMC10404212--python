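"""EEG distraction descriptor: band filtering, epoching, and spectral features.

The descriptor characterises a subject's response to ambient distraction
through three feature families computed on alpha (8-13 Hz) and beta
(13-30 Hz) band signals of occipito-temporal channels:

* **PSD features** — shape statistics of the raw-FFT power spectrum of each
  epoch: spectral concavity, in-band power variance, and the non-dominant
  power ratio. These operationalise spectral-distribution descriptors that
  the underlying literature names without formulas; the exact definitions
  used here are documented in docs/methods.md.
* **WPS (wavelet phase stability)** — modulus of the trial-averaged unit
  phasor of complex-Morlet wavelet phase, averaged over time; 1 means
  perfect inter-trial phase locking.
* **Coherence** — magnitude-squared coherence between channel pairs, from
  per-trial Hann-tapered auto-/cross-spectra averaged across trials.

One descriptor object is emitted per retained trial; the multi-trial
statistics (WPS, coherence) are computed over a sliding block of the most
recent trials and assigned to the block's last trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CHANNELS",
    "DEFAULT_BANDS",
    "DEFAULT_PAIRS",
    "EEGRecording",
    "EpochSet",
    "Spectrum",
    "WPSValue",
    "CoherenceValue",
    "fir_bandpass",
    "segment",
    "reject_artifacts",
    "psd",
    "psd_features",
    "wps",
    "coherence",
    "build_descriptor",
]

DEFAULT_CHANNELS = ("T5", "T6", "O1", "OZ", "O2")
DEFAULT_BANDS = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
DEFAULT_PAIRS = (("O1", "OZ"), ("OZ", "O2"))

# omega0 of the analytic Morlet wavelet; 6 cycles is the standard choice
# trading time against frequency resolution for band-limited EEG.
MORLET_OMEGA0 = 6.0


@dataclass
class EEGRecording:
    """Multichannel recording in microvolts with trial-onset markers."""

    samples: np.ndarray  # channels x time
    fs: float = 512.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names must match the channel dimension")
        if self.onsets.size and (
            np.any(np.diff(self.onsets) <= 0)
            or self.onsets[0] < 0
            or self.onsets[-1] >= self.samples.shape[1]
        ):
            raise ValueError("onsets must be strictly increasing and in range")


@dataclass
class EpochSet:
    """Stack of equal-length trials: trials x channels x samples."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    kept_trial_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name) if isinstance(
                self.channel_names, list
            ) else list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass(frozen=True)
class Spectrum:
    """Raw-FFT spectrum of one segment: complex coefficients and power |x(k)|^2 / N."""

    coeffs: np.ndarray
    power: np.ndarray
    N: int
    fs: float

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.fftfreq(self.N, d=1.0 / self.fs)


@dataclass(frozen=True)
class WPSValue:
    gamma: float
    scale: float
    tau_range: tuple[int, int]
    M: int


@dataclass(frozen=True)
class CoherenceValue:
    cxy: np.ndarray
    freqs: np.ndarray
    band_mean: float
    pair: tuple[str, str]


# -- preprocessing -----------------------------------------------------


def fir_bandpass(
    rec: EEGRecording, lo_hz: float, hi_hz: float, taps: int = 513
) -> EEGRecording:
    """Linear-phase windowed-sinc bandpass, group delay compensated.

    Each channel is reflection-padded by half the filter length and
    convolved, so the output is time-aligned with the input and of equal
    length. DC and out-of-band components are suppressed.
    """
    if not (0 < lo_hz < hi_hz < rec.fs / 2):
        raise ValueError("band must satisfy 0 < lo < hi < Nyquist")
    if taps % 2 == 0:
        raise ValueError("taps must be odd for integer group delay")
    h = sps.firwin(taps, [lo_hz, hi_hz], pass_zero=False, fs=rec.fs)
    pad = taps // 2
    padded = np.pad(rec.samples, ((0, 0), (pad, pad)), mode="reflect")
    out = sps.fftconvolve(padded, h[None, :], mode="valid", axes=1)
    return EEGRecording(out, rec.fs, rec.channel_names, rec.onsets.copy())


def segment(rec: EEGRecording, epoch_len_s: float = 1.0) -> EpochSet:
    """Cut one epoch per trial onset (default 1 s from onset).

    Onsets whose window runs past the end of the recording are dropped with
    a warning rather than truncated.
    """
    n = int(round(epoch_len_s * rec.fs))
    if n < 1:
        raise ValueError("epoch length too short")
    epochs = []
    kept = []
    for i, onset in enumerate(rec.onsets):
        if onset + n > rec.samples.shape[1]:
            logger.warning("trial %d dropped: onset too close to end", i)
            continue
        epochs.append(rec.samples[:, onset : onset + n])
        kept.append(i)
    return EpochSet(
        np.array(epochs) if epochs else np.empty((0, rec.samples.shape[0], n)),
        rec.fs,
        tuple(rec.channel_names),
        tuple(kept),
    )


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop trials whose absolute amplitude exceeds the threshold anywhere.

    Amplitudes strictly larger than ``threshold_uv`` (default 100 uV) are
    taken as body movements or other artefacts; a peak exactly at the
    threshold is kept.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if epochs.n_trials == 0:
        raise ValueError("no trials to screen")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not np.any(keep):
        raise ValueError("all trials rejected as artefacts")
    return EpochSet(
        epochs.data[keep],
        epochs.fs,
        epochs.channel_names,
        tuple(np.asarray(epochs.kept_trial_ids)[keep].tolist()),
    )


# -- spectral features -------------------------------------------------


def psd(x: np.ndarray, fs: float) -> Spectrum:
    """Raw-FFT power spectrum: P(k) = |X(k)|^2 / N over the full DFT grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-d with at least two samples")
    coeffs = np.fft.fft(x)
    power = np.abs(coeffs) ** 2 / x.size
    return Spectrum(coeffs=coeffs, power=power, N=x.size, fs=fs)


def psd_features(
    spec: Spectrum, band: tuple[float, float]
) -> tuple[float, float, float]:
    """Shape statistics of the in-band power spectrum.

    Returns ``(concavity, power_variance, nondominant_ratio)``:
    the quadratic coefficient of a least-squares parabola on log10(P + 1e-12)
    over the in-band bins; the variance of the in-band power values; and
    1 minus the fraction of in-band power within +-1 Hz of the in-band peak.
    """
    lo, hi = band
    if not (0 <= lo < hi <= spec.fs / 2):
        raise ValueError("band must lie within [0, Nyquist]")
    freqs = spec.freqs[: spec.N // 2 + 1]
    freqs = np.abs(freqs)
    power = spec.power[: freqs.size]
    in_band = (freqs >= lo) & (freqs <= hi)
    if in_band.sum() < 3:
        raise ValueError("need at least three in-band bins")
    f = freqs[in_band]
    p = power[in_band]
    concavity = float(np.polyfit(f, np.log10(p + 1e-12), 2)[0])
    power_variance = float(np.var(p))
    total = float(p.sum())
    if total == 0.0:
        nondominant = 0.0
    else:
        peak_f = f[np.argmax(p)]
        near = np.abs(f - peak_f) <= 1.0
        nondominant = 1.0 - float(p[near].sum()) / total
    return concavity, power_variance, nondominant


def _morlet_wavelet_name() -> str:
    # cmorB-C with 2*pi*C = omega0 and B = 2 reproduces the analytic Morlet
    # exp(i*omega0*t) * exp(-t^2/2) up to normalisation (phase unaffected)
    c = MORLET_OMEGA0 / (2.0 * np.pi)
    return f"cmor2.0-{c:.6f}"


def _morlet_phases(
    data: np.ndarray, fs: float, centre_hz: float
) -> tuple[np.ndarray, float]:
    """Wavelet phase of each trial at the band-centre scale.

    ``data`` is trials x samples; returns (phases trials x samples, scale
    in samples)."""
    name = _morlet_wavelet_name()
    c = MORLET_OMEGA0 / (2.0 * np.pi)
    scale = c * fs / centre_hz
    coeffs, _ = pywt.cwt(data, [scale], name, sampling_period=1.0 / fs, axis=-1)
    return np.angle(coeffs[0]), scale


def _edge_margin(scale: float, n_samples: int) -> int:
    # half the effective wavelet support: 2 time-domain standard deviations
    # of the Gaussian envelope (sigma_t = scale * sqrt(B/2) = scale for B=2)
    margin = int(round(2.0 * scale))
    return min(margin, max((n_samples - 2) // 2, 0))


def wps(
    epochs: EpochSet, channel: str, band: tuple[float, float]
) -> WPSValue:
    """Wavelet phase stability of one channel over the trials of the set.

    A complex Morlet wavelet at the band-centre frequency extracts the
    instantaneous phase of every trial; at each time point the modulus of
    the mean unit phasor across trials measures phase clustering (1 =
    perfect locking, ~1/sqrt(M) for random phases). The returned gamma
    averages that modulus over time, excluding half a wavelet support at
    each edge.
    """
    if epochs.n_trials < 2:
        raise ValueError("WPS needs at least two trials")
    ch = epochs.channel_index(channel)
    lo, hi = band
    centre = 0.5 * (lo + hi)
    phases, scale = _morlet_phases(epochs.data[:, ch, :], epochs.fs, centre)
    n = phases.shape[1]
    margin = _edge_margin(scale, n)
    interior = slice(margin, n - margin)
    resultant = np.abs(np.mean(np.exp(1j * phases[:, interior]), axis=0))
    gamma = float(np.clip(resultant.mean(), 0.0, 1.0))
    return WPSValue(
        gamma=gamma, scale=scale, tau_range=(margin, n - margin),
        M=epochs.n_trials,
    )


def coherence(
    epochs: EpochSet, ch_a: str, ch_b: str, band: tuple[float, float]
) -> CoherenceValue:
    """Magnitude-squared coherence between two channels, averaged over trials.

    Per-trial Hann-tapered auto- and cross-spectra are averaged across the
    trials of the set before forming |Pxy|^2 / (Pxx Pyy); single-segment
    coherence would be identically 1, hence the two-trial minimum. Bins with
    zero auto-power are excluded; values are clipped to [0, 1].
    """
    if epochs.n_trials < 2:
        raise ValueError("coherence needs at least two trials")
    ia, ib = epochs.channel_index(ch_a), epochs.channel_index(ch_b)
    x = epochs.data[:, ia, :]
    y = epochs.data[:, ib, :]
    n = x.shape[1]
    win = sps.windows.hann(n, sym=False)
    X = np.fft.rfft(x * win, axis=1)
    Y = np.fft.rfft(y * win, axis=1)
    pxx = np.mean(np.abs(X) ** 2, axis=0)
    pyy = np.mean(np.abs(Y) ** 2, axis=0)
    pxy = np.mean(X * np.conj(Y), axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    valid = (pxx > 0) & (pyy > 0)
    cxy = np.full(freqs.size, np.nan)
    cxy[valid] = np.clip(
        np.abs(pxy[valid]) ** 2 / (pxx[valid] * pyy[valid]), 0.0, 1.0
    )
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi) & valid
    if not np.any(in_band):
        raise ValueError("no valid in-band frequency bins")
    band_mean = float(np.mean(cxy[in_band]))
    return CoherenceValue(
        cxy=cxy, freqs=freqs, band_mean=band_mean, pair=(ch_a, ch_b)
    )


# -- descriptor assembly ----------------------------------------------


def build_descriptor(
    epochs_by_band: dict[str, EpochSet],
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    bands: dict[str, tuple[float, float]] | None = None,
    block: int = 10,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-trial descriptor table.

    PSD features are per-trial; WPS and coherence are computed over the
    block of the ``block`` most recent trials ending at each trial (the
    first trials fall back to the earliest computable block) so that every
    trial receives one value. Feature names follow
    ``<family>_<channel(s)>_<band>[_<subfeature>]``.

    ``labels``, when given, is written to a ``class`` column (one entry per
    trial of the band epoch sets).
    """
    bands = dict(bands) if bands is not None else dict(DEFAULT_BANDS)
    missing = set(bands) - set(epochs_by_band)
    if missing:
        raise ValueError(f"missing epoch sets for bands: {sorted(missing)}")
    ref = epochs_by_band[next(iter(bands))]
    n_trials = ref.n_trials
    for es in epochs_by_band.values():
        if es.n_trials != n_trials:
            raise ValueError("band epoch sets must align trial-for-trial")
    for ch in channels:
        ref.channel_index(ch)  # raises KeyError on unknown channel

    columns: dict[str, np.ndarray] = {}
    for band_name, band in bands.items():
        es = epochs_by_band[band_name]
        # per-trial PSD shape features
        for ch in channels:
            ci = es.channel_index(ch)
            conc = np.empty(n_trials)
            pvar = np.empty(n_trials)
            ndom = np.empty(n_trials)
            for t in range(n_trials):
                spec = psd(es.data[t, ci, :], es.fs)
                conc[t], pvar[t], ndom[t] = psd_features(spec, band)
            columns[f"psd_{ch}_{band_name}_concavity"] = conc
            columns[f"psd_{ch}_{band_name}_variance"] = pvar
            columns[f"psd_{ch}_{band_name}_nondominant"] = ndom
        # block-wise WPS from phases computed once per channel
        centre = 0.5 * (band[0] + band[1])
        for ch in channels:
            ci = es.channel_index(ch)
            phases, scale = _morlet_phases(es.data[:, ci, :], es.fs, centre)
            n = phases.shape[1]
            margin = _edge_margin(scale, n)
            phasors = np.exp(1j * phases[:, margin : n - margin])
            columns[f"wps_{ch}_{band_name}"] = _block_wps(phasors, block)
        # block-wise coherence per pair
        for ch_a, ch_b in pairs:
            vals = np.empty(n_trials)
            for t in range(n_trials):
                s, e = _block_bounds(t, n_trials, block)
                sub = EpochSet(
                    es.data[s:e], es.fs, es.channel_names,
                    tuple(range(s, e)),
                )
                vals[t] = coherence(sub, ch_a, ch_b, band).band_mean
            columns[f"coh_{ch_a}-{ch_b}_{band_name}"] = vals

    table = pd.DataFrame(columns)
    if labels is not None:
        if len(labels) != n_trials:
            raise ValueError("labels must match the trial count")
        table["class"] = list(labels)
    return table


def _block_bounds(t: int, n_trials: int, block: int) -> tuple[int, int]:
    """Trial slice of the block ending at t; first trials use the earliest
    two-trial block so every trial gets a value."""
    s = max(0, t - block + 1)
    e = t + 1
    if e - s < 2:  # cold start: peek at the first computable block
        s, e = 0, min(2, n_trials)
    return s, e


def _block_wps(phasors: np.ndarray, block: int) -> np.ndarray:
    """Per-trial WPS over the sliding block, from precomputed unit phasors."""
    n_trials = phasors.shape[0]
    out = np.empty(n_trials)
    for t in range(n_trials):
        s, e = _block_bounds(t, n_trials, block)
        resultant = np.abs(np.mean(phasors[s:e], axis=0))
        out[t] = float(np.clip(resultant.mean(), 0.0, 1.0))
    return out
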