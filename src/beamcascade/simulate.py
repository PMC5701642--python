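"""Simulated interictal-spike measurements.

A parametric biphasic spike template (sharp transient followed by a slow
wave) stands in for an averaged patient spike.  The template is inserted at
a small number of onsets into an otherwise quiet multichannel recording,
and white sensor noise with an exactly realized per-channel variance is
added on top.  Default protocol: 1,200 samples/s, a 530 ms (636-sample)
template, two firings in a 20 s (24,000-sample) measurement, peak source
amplitude 100 nAm, and noise variances of 1e-3 / 1 µV² (EEG) or 1 / 1e3 fT²
(MEG) for the low / high noise scenarios.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: (low, high) sensor-noise variances per modality, in µV² (EEG) / fT² (MEG)
NOISE_VARIANCES = {"eeg": (1e-3, 1.0), "meg": (1.0, 1e3)}

#: leadfield (SI) x amplitude (nAm) -> sensor units (µV for EEG, fT for MEG)
UNIT_SCALE = {"eeg": 1e-3, "meg": 1e6}
SENSOR_UNITS = {"eeg": "µV", "meg": "fT"}


@dataclass
class SpikeWaveform:
    """Dimensionless source-waveform template, peak-normalized to 1."""

    samples: np.ndarray
    rate: float
    duration_ms: float

    def __len__(self):
        return self.samples.size


def make_spike_waveform(rate: float = 1200.0, duration_ms: float = 530.0,
                        sharp_center_ms: float = 130.0, sharp_width_ms: float = 70.0,
                        slow_center_ms: float = 300.0, slow_width_ms: float = 250.0,
                        slow_fraction: float = 0.45) -> SpikeWaveform:
    """Biphasic difference-of-Gaussians spike template.

    A sharp negative transient (total width ~``sharp_width_ms``) followed by
    a slower positive wave (~``slow_width_ms``) of relative amplitude
    ``slow_fraction``.  The template has exactly round(rate*duration/1000)
    samples, peak absolute value 1, and starts/ends within 1% of the peak.
    """
    if rate <= 0 or duration_ms <= 0:
        raise ValueError("rate and duration must be positive")
    n = int(round(rate * duration_ms / 1000.0))
    t = np.arange(n) / rate * 1000.0  # ms
    s1 = sharp_width_ms / 4.0
    s2 = slow_width_ms / 4.0
    w = (-np.exp(-0.5 * ((t - sharp_center_ms) / s1) ** 2)
         + slow_fraction * np.exp(-0.5 * ((t - slow_center_ms) / s2) ** 2))
    w /= np.max(np.abs(w))
    return SpikeWaveform(samples=w, rate=float(rate), duration_ms=float(duration_ms))


@dataclass
class Measurement:
    """Multichannel recording (channels x samples).

    EEG data are in µV, MEG in fT.  ``truth`` optionally records the
    simulated source (position, orientation, onsets, amplitude) for scoring.
    """

    data: np.ndarray
    rate: float
    modality: str
    units: str = ""
    truth: Optional[dict] = field(default=None)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Measurement":
        return replace(self, data=self.data.copy(),
                       truth=None if self.truth is None else dict(self.truth))


def assemble_measurement(gain_column: np.ndarray, waveform: SpikeWaveform,
                         onsets, duration_s: float = 20.0, rate: float = 1200.0,
                         amplitude_nam: float = 100.0, modality: str = "eeg",
                         truth_extra: Optional[dict] = None) -> Measurement:
    """Noise-free measurement of one source firing at the given onsets.

    ``gain_column`` is the source's 1-D leadfield in SI units; the output is
    gain * (amplitude * waveform) inserted at each onset (sample indices) and
    exactly zero elsewhere, converted to µV (EEG) or fT (MEG).
    """
    gain_column = np.asarray(gain_column, float)
    total = int(round(rate * duration_s))
    nw = len(waveform)
    onsets = sorted(int(o) for o in np.atleast_1d(onsets))
    for a, b in zip(onsets, onsets[1:]):
        if b < a + nw:
            raise ValueError("spike onsets overlap")
    if onsets and (onsets[0] < 0 or onsets[-1] + nw > total):
        raise ValueError("spike window extends beyond the measurement")

    src = np.zeros(total)
    for o in onsets:
        src[o:o + nw] = amplitude_nam * waveform.samples
    data = gain_column[:, None] * src[None, :] * UNIT_SCALE[modality]
    truth = {"onsets": onsets, "amplitude_nam": float(amplitude_nam),
             "rate": float(rate), "n_samples": total}
    if truth_extra:
        truth.update(truth_extra)
    return Measurement(data=data, rate=float(rate), modality=modality,
                       units=SENSOR_UNITS[modality], truth=truth)


def white_noise_matrix(n_channels: int, n_samples: int, variance: float,
                       seed: int) -> np.ndarray:
    """Gaussian noise whose realized per-channel sample variance is exact.

    Each channel is drawn independently, demeaned and rescaled so that its
    empirical variance equals ``variance`` exactly.  The same seed at
    variances v and k*v yields matrices related by the factor sqrt(k)
    exactly, mirroring a single shared noise realization at varying scale.
    """
    if variance < 0:
        raise ValueError("noise variance must be >= 0")
    if variance == 0:
        return np.zeros((n_channels, n_samples))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_channels, n_samples))
    z -= z.mean(axis=1, keepdims=True)
    z /= z.std(axis=1, keepdims=True)
    return z * np.sqrt(variance)


def add_white_noise(meas: Measurement, variance: float, seed: int) -> Measurement:
    """Return a copy of ``meas`` with exact-variance white noise added.

    The noise is added per channel, before any re-referencing; apply
    :func:`common_average_reference` afterwards for EEG if desired.
    """
    out = meas.copy()
    out.data = out.data + white_noise_matrix(meas.n_channels, meas.n_samples,
                                             variance, seed)
    return out


def common_average_reference(meas: Measurement) -> Measurement:
    """Subtract the instantaneous mean over channels (EEG referencing)."""
    out = meas.copy()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    return out


def demean_channels(meas: Measurement) -> Measurement:
    """Remove each channel's temporal mean (zero-mean assumption)."""
    out = meas.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out
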