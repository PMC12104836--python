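"""Multichannel synthetic icEEG signals.

Each clean channel is a 1/f background (white-noise FFT amplitudes shaped
as f^(-alpha/2)) plus band-limited oscillations whose variances follow the
channel's band-power profile, plus a narrow line-noise sinusoid.  Artifact
channels are replaced with large-amplitude flat-spectrum noise; spiking
channels get superimposed ~70 ms biphasic transients.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from normkit.bands import DEFAULT_BAND_EDGES

SPIKE_WIDTH_S = 0.07
SPIKE_AMPLITUDE = 8.0
ARTIFACT_SCALE = 30.0


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-variance noise with PSD proportional to f^(-alpha)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance noise confined to [low, high) Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < low) | (f >= high)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_kernel(fs: float) -> np.ndarray:
    """Biphasic transient: one full sine period over the spike width."""
    t = np.arange(int(round(SPIKE_WIDTH_S * fs))) / fs
    return SPIKE_AMPLITUDE * np.sin(2.0 * np.pi * t / SPIKE_WIDTH_S)


def generate_signal(
    profiles: Sequence[Mapping[str, float]] | Mapping[str, float],
    duration: float,
    fs: float,
    line_noise_hz: float = 50.0,
    seed: int = 0,
    *,
    n_channels: int | None = None,
    band_edges: Mapping[str, tuple[float, float]] | None = None,
    alpha: float = 2.0,
    background_var: float = 1.0,
    osc_strength: float = 25.0,
    line_var: float = 0.5,
    artifact_channels: Sequence[int] = (),
    spiking_channels: Sequence[int] = (),
    spike_rate_per_min: float = 1.0,
) -> np.ndarray:
    """Synthesize a channels x samples array.

    ``profiles`` is either one band-power mapping applied to every channel
    (give ``n_channels``) or a sequence with one mapping per channel.  A
    band's oscillation variance is ``osc_strength * background_var *
    weight``.  ``artifact_channels`` / ``spiking_channels`` are row
    indices.  Identical arguments (including ``seed``) yield bit-identical
    arrays.
    """
    if line_noise_hz > 0 and fs <= 2 * line_noise_hz:
        raise ValueError(
            f"fs={fs} cannot represent a {line_noise_hz} Hz line-noise peak"
        )
    if isinstance(profiles, Mapping):
        if n_channels is None:
            raise ValueError("n_channels is required with a single shared profile")
        profiles = [profiles] * n_channels
    edges = dict(band_edges or DEFAULT_BAND_EDGES)
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration * fs too small")
    out = np.empty((len(profiles), n))
    t = np.arange(n) / fs
    artifact = set(artifact_channels)
    spiking = set(spiking_channels)
    for c, profile in enumerate(profiles):
        rng = np.random.default_rng([int(seed), c])
        if c in artifact:
            out[c] = ARTIFACT_SCALE * rng.standard_normal(n)
            continue
        x = np.sqrt(background_var) * _shaped_noise(rng, n, fs, alpha)
        for band, weight in profile.items():
            if weight <= 0:
                continue
            low, high = edges[band]
            var = osc_strength * background_var * float(weight)
            x = x + np.sqrt(var) * _band_noise(rng, n, fs, low, high)
        if line_noise_hz > 0 and line_var > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + np.sqrt(2 * line_var) * np.sin(2 * np.pi * line_noise_hz * t + phase)
        if c in spiking:
            kernel = _spike_kernel(fs)
            n_spikes = rng.poisson(spike_rate_per_min * duration / 60.0)
            starts = rng.integers(0, max(n - len(kernel), 1), size=n_spikes)
            for s in starts:
                x[s : s + len(kernel)] += kernel[: n - s]
        out[c] = x
    return out
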