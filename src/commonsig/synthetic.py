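"""Synthetic multichannel LFP generator with known ground truth.

Emulates the fly preparation the pipeline was designed around: 15 unipolar
channels on a 25 μm-pitch linear array, sampled at 1000 Hz in 8 epochs of
2.25 s. Each channel is

    y_i(t) = x_i(t) + a_i vc(t) - r(t)  [+ optional 50 Hz line sinusoid]

where

  * x_i is neural activity with two components, reflecting that slow LFP
    components have a much larger spatial reach than fast ones: a dominant
    slow AR(1) rhythm (coefficient ``slow_ar``) whose innovations are
    spatially smoothed across the array (Gaussian profile; adjacent-channel
    correlation ``slow_corr_adjacent``, decaying with distance), plus a
    weak fast AR(1) component (``fast_ar``) independent across channels.
    Total power decays with frequency;
  * r is a global white reference signal with variance ``reference_power``
    entering every channel identically (non-silent reference electrode);
  * vc is a white volume-conducted source at the array center, entering
    channel i attenuated by a_i = exp(-distance_i / vc_lambda_um).

Defaults put the high-frequency neural-to-common ratio near 0.4, i.e.
high-frequency unipolar coherence near 0.5 — the regime reported for fly
LFP referenced in the thorax — while keeping adjacent channels' neural
activity highly similar (so bipolar derivations are much smaller than
unipolar signals) and high-frequency activity local (so bipolar
derivations decorrelate except through a shared unipolar channel). The
analytic ground truth (per-channel neural, reference and volume-conduction
power spectra, and the implied NCR) is derived from the configuration,
never estimated from the samples.

The module also provides the four canonical two-node scenarios
(connected / disconnected, without / with a flat common signal whose power
equals the mean neural power) both as analytic spectral matrices and as
simulated recordings. The disconnected time-domain system is realized as
two *independent* streams whose marginal spectra match the connected
system's: channel 1 is the same AR(1); channel 2 is white noise filtered
by the minimum-phase system obtained from cepstral factorization of the
connected S_22.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy.signal import fftconvolve, lfilter

from .ar_spectral import (
    FrequencyGrid,
    SpectralMatrix,
    ar_spectral_matrix,
    connected_model,
    scenario_model,
    simulate_timeseries,
)
from .common_signal import ChannelLayout, CommonSignalSpec, inject_common, mean_neural_power
from .pipeline import Recording

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_session",
    "ground_truth_for",
    "reference_power_for_band_ncr",
    "scenario_recording",
    "scenario_spectral_matrix",
]


class GeneratorConfig(BaseModel):
    """Study conditions for :func:`generate_session`; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_channels: int = 15
    fs_hz: float = 1000.0
    n_epochs: int = 8
    epoch_s: float = 2.25
    pitch_um: float = 25.0
    slow_ar: float = 0.97
    slow_var: float = 1.0
    slow_corr_adjacent: float = 0.9
    fast_ar: float = 0.3
    fast_var: float = 0.08
    reference_power: float = 0.13
    vc_power: float = 0.02
    vc_lambda_um: float = 100.0
    line_amp_50hz: float = 0.0
    seed: int = 0

    def validate_physical(self) -> None:
        if (
            min(
                self.slow_var,
                self.fast_var,
                self.reference_power,
                self.vc_power,
                self.line_amp_50hz,
            )
            < 0
        ):
            raise ValueError("variances and amplitudes must be nonnegative")
        if self.vc_lambda_um <= 0:
            raise ValueError("volume-conduction decay length must be positive")
        if not (0.0 <= self.slow_corr_adjacent < 1.0):
            raise ValueError("slow_corr_adjacent must lie in [0, 1)")
        if max(abs(self.slow_ar), abs(self.fast_ar)) >= 1:
            raise ValueError("neural AR coefficients must be stationary (|phi| < 1)")
        n = self.epoch_s * self.fs_hz
        if abs(n - round(n)) > 1e-9 or int(round(n)) % 2:
            raise ValueError("epoch_s * fs_hz must be an even integer sample count")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-channel spectra implied by a GeneratorConfig.

    Spectra are two-sided densities (variance / fs for white signals), the
    same convention the multitaper pipeline uses, so ratios are directly
    comparable. ``ncr`` is neural power over total common-signal power
    (reference + attenuated volume conduction), per channel per frequency.
    """

    freqs: np.ndarray
    neural_psd: np.ndarray  # (n_freq, n_channels)
    reference_psd: np.ndarray  # (n_freq,)
    vc_psd: np.ndarray  # (n_freq, n_channels)
    ncr: np.ndarray  # (n_freq, n_channels)

    def band_ncr(self, band_hz: tuple[float, float]) -> float:
        """Ground-truth NCR of the band-aggregated powers: ratio of the
        band-mean neural power to the band-mean common-signal power (the
        quantity a coherence-based band estimate targets)."""
        mask = (self.freqs >= band_hz[0]) & (self.freqs <= band_hz[1])
        if not np.any(mask):
            raise ValueError(f"band {band_hz} contains no grid points")
        common = self.reference_psd[:, None] + self.vc_psd
        return float(np.mean(self.neural_psd[mask]) / np.mean(common[mask]))


def _vc_attenuation(config: GeneratorConfig) -> np.ndarray:
    """Per-channel attenuation of the central volume-conduction source."""
    pos = config.pitch_um * np.arange(config.n_channels)
    center = 0.5 * (pos[0] + pos[-1])
    return np.exp(-np.abs(pos - center) / config.vc_lambda_um)


def _smooth_across_channels(field: np.ndarray, corr_adjacent: float) -> np.ndarray:
    """Spatially correlate a white (time, channel) field with a Gaussian
    profile: corr at channel offset d is corr_adjacent**(d^2).

    The kernel has unit L2 norm so per-channel variance is preserved; the
    field is generated wider than the array and cropped, so edge channels
    have the same statistics as interior ones.
    """
    if corr_adjacent <= 0:
        return field
    # corr(d) = exp(-d^2 / (4 s^2))  ->  4 s^2 = -1 / ln(corr_adjacent)
    s2 = -0.25 / np.log(corr_adjacent)
    half = int(np.ceil(4 * np.sqrt(2 * s2))) + 1
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-(offsets**2) / (4.0 * s2))
    kernel /= np.linalg.norm(kernel)
    out = np.zeros_like(field[:, : field.shape[1] - 2 * half])
    m = out.shape[1]
    for k, w in zip(offsets, kernel):
        out += w * field[:, half + k : half + k + m]
    return out


def _ar1_psd(phi: float, variance: float, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Two-sided density of an AR(1) process with the given total variance."""
    innov_var = variance * (1.0 - phi**2)
    theta = 2.0 * np.pi * freqs / fs
    return innov_var / (fs * np.abs(1.0 - phi * np.exp(-1j * theta)) ** 2)


def ground_truth_for(config: GeneratorConfig, epoch_len: int | None = None) -> GroundTruth:
    """Analytic ground truth implied by a configuration (no sampling)."""
    config.validate_physical()
    fs = config.fs_hz
    epoch_len = epoch_len or int(round(config.epoch_s * fs))
    m = config.n_channels
    freqs = np.fft.rfftfreq(epoch_len, d=1.0 / fs)
    neural = _ar1_psd(config.slow_ar, config.slow_var, freqs, fs) + _ar1_psd(
        config.fast_ar, config.fast_var, freqs, fs
    )
    neural_psd = neural[:, None] * np.ones(m)
    reference_psd = np.full(freqs.size, config.reference_power / fs)
    atten = _vc_attenuation(config)
    vc_psd = (config.vc_power / fs) * (atten**2)[None, :] * np.ones((freqs.size, 1))
    common_psd = reference_psd[:, None] + vc_psd
    with np.errstate(divide="ignore"):  # no common signal -> NCR = inf
        ncr = neural_psd / common_psd
    return GroundTruth(
        freqs=freqs,
        neural_psd=neural_psd,
        reference_psd=reference_psd,
        vc_psd=vc_psd,
        ncr=ncr,
    )


def reference_power_for_band_ncr(
    target_ncr: float, config: GeneratorConfig | None = None,
    band_hz: tuple[float, float] = (200.0, 450.0),
) -> float:
    """Reference-signal variance that sets the band-mean ground-truth NCR.

    Solves mean_band(neural) / (reference/fs + mean_band(vc)) = target_ncr
    analytically from the configuration. Raises if volume conduction alone
    already pushes the band NCR below the target.
    """
    if target_ncr <= 0:
        raise ValueError("target NCR must be positive")
    config = config or GeneratorConfig()
    truth = ground_truth_for(config)
    mask = (truth.freqs >= band_hz[0]) & (truth.freqs <= band_hz[1])
    neural = float(np.mean(truth.neural_psd[mask]))
    vc = float(np.mean(truth.vc_psd[mask]))
    ref = config.fs_hz * (neural / target_ncr - vc)
    if ref <= 0:
        raise ValueError(
            f"band NCR {target_ncr} unreachable: volume conduction alone is too strong"
        )
    return ref


def generate_session(config: GeneratorConfig | None = None) -> tuple[Recording, GroundTruth]:
    """Generate a unipolar recording plus its analytic ground truth.

    Deterministic given ``config.seed``; all randomness flows through one
    seeded generator and epoch boundaries are deterministic.
    """
    config = config or GeneratorConfig()
    config.validate_physical()
    rng = np.random.default_rng(config.seed)
    m = config.n_channels
    fs = config.fs_hz
    epoch_len = int(round(config.epoch_s * fs))
    n = config.n_epochs * epoch_len
    burn = 1000
    total = n + burn

    # slow, spatially coherent neural rhythm
    if config.slow_corr_adjacent > 0:
        s2 = -0.25 / np.log(config.slow_corr_adjacent)
        half = int(np.ceil(4 * np.sqrt(2 * s2))) + 1
    else:
        half = 0
    slow_innov = _smooth_across_channels(
        rng.standard_normal((total, m + 2 * half)), config.slow_corr_adjacent
    )
    slow_innov *= np.sqrt(config.slow_var * (1.0 - config.slow_ar**2))
    slow = lfilter([1.0], [1.0, -config.slow_ar], slow_innov, axis=0)

    # fast, spatially independent neural activity
    fast_innov = rng.standard_normal((total, m)) * np.sqrt(
        config.fast_var * (1.0 - config.fast_ar**2)
    )
    fast = lfilter([1.0], [1.0, -config.fast_ar], fast_innov, axis=0)

    x = slow + fast
    r = np.sqrt(config.reference_power) * rng.standard_normal(total)
    vc = np.sqrt(config.vc_power) * rng.standard_normal(total)
    atten = _vc_attenuation(config)

    y = x + atten[None, :] * vc[:, None] - r[:, None]
    if config.line_amp_50hz > 0:
        t = np.arange(total) / fs
        phase = rng.uniform(0, 2 * np.pi)
        y += config.line_amp_50hz * np.sin(2 * np.pi * 50.0 * t + phase)[:, None]
    y = y[burn:]

    recording = Recording(
        samples=y,
        fs=fs,
        layout=ChannelLayout.linear(m, pitch_um=config.pitch_um),
        label="unipolar",
        n_epochs=config.n_epochs,
        epoch_s=config.epoch_s,
    )
    return recording, ground_truth_for(config, epoch_len)


# ---------------------------------------------------------------------------
# Canonical two-node scenarios
# ---------------------------------------------------------------------------

def scenario_spectral_matrix(which: int, grid: FrequencyGrid | None = None) -> SpectralMatrix:
    """Analytic spectral density matrix of scenario 1-4.

    1: unidirectionally connected; 2: disconnected with identical
    auto-spectra; 3/4: the same systems plus a flat common signal whose
    power equals the mean neural power across the grid.
    """
    grid = grid if grid is not None else FrequencyGrid.default()
    if which not in (1, 2, 3, 4):
        raise ValueError("scenario must be 1, 2, 3 or 4")
    Q1 = ar_spectral_matrix(connected_model(), grid)
    if which == 1:
        return Q1
    if which == 2:
        return scenario_model("disconnected", grid)
    u = CommonSignalSpec(kind="flat", level=mean_neural_power(Q1))
    base = Q1 if which == 3 else scenario_model("disconnected", grid)
    return inject_common(base, u)


def _minimum_phase_fir(psd_circle: np.ndarray) -> np.ndarray:
    """Minimum-phase impulse response whose |FFT|^2 equals the given
    full-circle power spectrum (real cepstrum method)."""
    s = np.asarray(psd_circle, dtype=float)
    if np.any(s <= 0):
        raise ValueError("power spectrum must be strictly positive")
    n = s.size
    cep = np.real(np.fft.ifft(0.5 * np.log(s)))  # cepstrum of the magnitude
    folded = np.zeros_like(cep)
    folded[0] = cep[0]
    folded[1 : (n + 1) // 2] = 2.0 * cep[1 : (n + 1) // 2]
    if n % 2 == 0:
        folded[n // 2] = cep[n // 2]
    h = np.real(np.fft.ifft(np.exp(np.fft.fft(folded))))
    return h


def scenario_recording(
    which: int,
    n_samples: int = 18000,
    seed: int = 0,
    fs: float = 1000.0,
    n_epochs: int = 1,
) -> Recording:
    """Time-domain realization of scenario 1-4 as a two-channel Recording.

    Scenarios 2/4 use two independent streams whose marginal spectra match
    the connected system's (spectral factorization of S_22); 3/4 add a
    white common signal with variance equal to the mean neural power.
    Deterministic given ``seed``.
    """
    if which not in (1, 2, 3, 4):
        raise ValueError("scenario must be 1, 2, 3 or 4")
    if n_samples % (2 * n_epochs):
        raise ValueError("n_samples must split into epochs of even length")
    rng = np.random.default_rng(seed)
    burn = 1000
    total = n_samples + burn

    model = connected_model()
    if which in (1, 3):
        y = simulate_timeseries(model, n_samples, rng, burn_in=burn)
    else:
        # independent streams with the connected system's marginal spectra
        a = -model.coeffs[1, 0, 0]
        e1 = rng.standard_normal(total)
        y1 = lfilter([1.0], [1.0, -a], e1)[burn:]
        n_circle = 4096
        grid = FrequencyGrid.default(n_circle // 2 + 1)
        s22 = ar_spectral_matrix(model, grid).auto_spectra()[:, 1]
        s22_circle = np.concatenate([s22, s22[-2:0:-1]])
        h = _minimum_phase_fir(s22_circle)
        e2 = rng.standard_normal(total + h.size)
        y2 = fftconvolve(e2, h, mode="full")[h.size + burn : h.size + total]
        y = np.column_stack([y1, y2])

    if which in (3, 4):
        level = mean_neural_power(ar_spectral_matrix(model, FrequencyGrid.default()))
        u = np.sqrt(level) * rng.standard_normal(n_samples)
        y = y + u[:, None]

    return Recording(
        samples=y,
        fs=fs,
        layout=ChannelLayout.linear(2, pitch_um=25.0),
        label="unipolar",
        n_epochs=n_epochs,
        epoch_s=n_samples / (n_epochs * fs),
    )
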