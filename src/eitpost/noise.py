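"""Raw-signal noise model for simulated EIT measurements.

Measurement hardware injects a 100 kHz sine and samples each channel 20
times per period; white Gaussian noise enters before the analog bandpass
filter.  The simulator reproduces this chain per channel: synthesize the
carrier at the channel's clean amplitude, add white Gaussian noise scaled
to the channel's SNR (power ratio of the clean wave to the noise), apply a
tenth-order zero-phase Butterworth bandpass centered on the carrier, and
retain the highest filtered peak (with the clean amplitude's sign) as the
demodulated voltage.

The SNR of real hardware depends strongly on the distance between the
drive pair and the measuring pair: above 50 dB next to the drive, below
10 dB at the opposite side.  :func:`snr_profile_adjacent` synthesizes a
smooth per-channel profile between those anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from eitpost.forward import frame_voltages, MeasurementFrame
from eitpost.protocol import StimulationProtocol

__all__ = [
    "NoiseModel",
    "snr_profile_adjacent",
    "estimate_snr",
    "synthesize_channel_waves",
    "synthesize_noisy_frame",
]


@dataclass
class NoiseModel:
    """Channel-dependent white-Gaussian noise on the raw carrier.

    Attributes
    ----------
    channel_snr_db : (n_channels,) array
        Per-channel SNR in dB of the raw (pre-filter) wave; ``inf``
        disables noise on a channel.
    carrier_hz, samples_per_period, n_periods, transient_periods
        Signal synthesis parameters: 100 kHz carrier sampled 20x per
        period for 64 periods; 24 periods at each end are excluded from
        peak extraction.  The narrowband (10%) tenth-order filter rings
        for tens of carrier periods, so a window much longer than the
        ringdown is needed for the no-noise round-trip to sit within
        filter ripple (<1%).
    filter_order
        Total pole count of the Butterworth bandpass (10), passband
        +/-10% around the carrier, applied forward-backward (zero phase).
    """

    channel_snr_db: np.ndarray
    carrier_hz: float = 100_000.0
    samples_per_period: int = 20
    n_periods: int = 64
    transient_periods: int = 24
    filter_order: int = 10
    passband_rel: float = 0.10

    def __post_init__(self):
        self.channel_snr_db = np.asarray(self.channel_snr_db, dtype=float)

    @property
    def sample_rate(self) -> float:
        return self.carrier_hz * self.samples_per_period

    @property
    def n_samples(self) -> int:
        return self.samples_per_period * self.n_periods

    def sos(self):
        """Second-order sections of the bandpass (order/2 biquads)."""
        lo = self.carrier_hz * (1 - self.passband_rel)
        hi = self.carrier_hz * (1 + self.passband_rel)
        return butter(self.filter_order // 2, [lo, hi], btype="bandpass",
                      fs=self.sample_rate, output="sos")


def snr_profile_adjacent(
    protocol: StimulationProtocol, snr_near_db: float = 55.0, snr_far_db: float = 8.0
) -> np.ndarray:
    """Smooth per-channel SNR profile for the adjacent protocol.

    SNR tapers with the ring distance between the drive pair and the
    measuring pair via a raised cosine: channels next to the drive sit at
    ``snr_near_db``, channels diametrically opposite at ``snr_far_db``.
    """
    n = protocol.n_electrodes
    pairs = protocol.channel_pairs()
    dist = np.minimum((pairs[:, 1] - pairs[:, 0]) % n, (pairs[:, 0] - pairs[:, 1]) % n)
    taper = 0.5 * (1.0 + np.cos(np.pi * dist / (n // 2)))
    return snr_far_db + (snr_near_db - snr_far_db) * taper


def estimate_snr(measured_wave: np.ndarray, expected_wave: np.ndarray) -> float:
    """SNR in dB: ``10 log10(mean(signal^2) / mean((measured-expected)^2))``.

    Returns ``inf`` when the residual is exactly zero.
    """
    measured = np.asarray(measured_wave, dtype=float)
    expected = np.asarray(expected_wave, dtype=float)
    if measured.shape != expected.shape:
        raise ValueError("waves must have equal length")
    resid = measured - expected
    p_noise = float(np.mean(resid * resid))
    p_sig = float(np.mean(expected * expected))
    if p_noise == 0.0:
        return np.inf
    return 10.0 * np.log10(p_sig / p_noise)


def synthesize_channel_waves(frame, noise: NoiseModel, rng: np.random.Generator):
    """Clean and noisy raw waves for every channel of a frame.

    Returns ``(clean, noisy)`` arrays of shape (n_channels, n_samples).
    The clean wave of channel c is ``v_c * sin(2 pi f t)``; noise standard
    deviation follows the channel SNR on the raw wave
    (``sigma^2 = (v_c^2 / 2) * 10**(-SNR/10)``).
    """
    v = frame_voltages(frame)
    t = np.arange(noise.n_samples) / noise.sample_rate
    clean = v[:, None] * np.sin(2.0 * np.pi * noise.carrier_hz * t)[None, :]
    snr = np.broadcast_to(noise.channel_snr_db, v.shape)
    p_sig = 0.5 * v * v
    with np.errstate(over="ignore"):
        sigma = np.sqrt(p_sig * 10.0 ** (-snr / 10.0))
    noisy = clean + sigma[:, None] * rng.standard_normal(clean.shape)
    return clean, noisy


def synthesize_noisy_frame(frame, noise: NoiseModel, rng: np.random.Generator) -> MeasurementFrame:
    """Push a clean frame through the raw-signal noise + filter pipeline.

    Per channel: synthesize the raw sine, add channel-SNR-scaled white
    noise, bandpass (zero phase), drop the edge transients, and keep the
    largest absolute filtered peak with the clean amplitude's sign.  With
    noise off the result equals the input to within filter ripple.
    """
    v = frame_voltages(frame)
    _, noisy = synthesize_channel_waves(v, noise, rng)
    filtered = sosfiltfilt(noise.sos(), noisy, axis=1)
    k = noise.transient_periods * noise.samples_per_period
    core = filtered[:, k : filtered.shape[1] - k]
    peaks = np.abs(core).max(axis=1)
    out = peaks * np.where(v >= 0, 1.0, -1.0)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("noise synthesis produced non-finite voltages")
    return MeasurementFrame(out)
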