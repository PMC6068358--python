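"""Common-signal contamination models and the coherence/NCR algebra.

A recorded "unipolar" channel is modeled as neural activity minus a signal
shared across electrodes,

    y_i(t) = x_i(t) - u(t),

where u(t) arises from a non-silent reference electrode and/or volume
conduction.  If u is independent of the neural signals, adding it simply
increments every entry of the cross-spectral density matrix by its power
U(omega)U*(omega); the channel auto-spectra become the sum of neural and
common power.  At frequencies where the neural signals themselves are
independent (e.g. implausibly high frequencies for genuine coupling), the
induced coherence depends on a single number, the neural-to-common signal
ratio NCR = (neural power)/(common power):

    C = 1 / (NCR + 1)^2          and inversely       NCR = 1/sqrt(C) - 1.

So observing coherence 0.25 at high frequencies suggests a common signal as
strong as the neural activity (NCR = 1), and coherence 0.5 suggests the
common signal dominates (NCR ~ 0.41).

Bipolar derivation — differencing adjacent channels — cancels any common
signal that enters both electrodes identically.  But two bipolar channels
built from a shared unipolar channel re-introduce a common signal: the
shared channel itself, bounding their coherence by the same 1/(NCR+1)^2
law (0.25 under equal neural power).

The common signal can be decomposed further into a global reference term
r(t) and a distance-decaying volume-conduction term vc_i(t),
y_i = x_i + vc_i - r; this package models the vc attenuation as
exp(-distance/lambda).  Only the qualitative prediction — high-frequency
coherence decaying with electrode separation under volume conduction — is
carried through; the full closed-form coherence for that case is out of
scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .ar_spectral import FrequencyGrid, SpectralMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import Recording

__all__ = [
    "CommonSignalSpec",
    "ChannelLayout",
    "inject_common",
    "mean_neural_power",
    "ncr_from_coherence",
    "coherence_from_ncr",
    "bipolar_derive",
    "shared_bipolar_coherence",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode positions (μm) along a linear array, strictly increasing."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("positions must be a 1-D array")
        if np.any(np.diff(p) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", p)

    @classmethod
    def linear(cls, n_channels: int, pitch_um: float = 25.0, start_um: float = 0.0) -> "ChannelLayout":
        return cls(start_um + pitch_um * np.arange(n_channels))

    @property
    def n_channels(self) -> int:
        return int(self.positions.size)

    def midpoints(self) -> "ChannelLayout":
        """Layout of adjacent-pair midpoints (positions of bipolar channels)."""
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels to form midpoints")
        return ChannelLayout(0.5 * (self.positions[:-1] + self.positions[1:]))


@dataclass(frozen=True)
class CommonSignalSpec:
    """Power spectrum of a common signal u(t) assumed independent of the
    neural system.

    kinds:
      * ``flat``: U U*(omega) = level at every frequency (white u).
      * ``one_over_f``: U U*(omega) = k / (omega + omega0); omega0 > 0 keeps
        the omega = 0 point finite.
      * ``custom``: arbitrary nonnegative per-frequency power array.
    """

    kind: str = "flat"
    level: float = 1.0
    k: float = 1.0
    omega0: float = 0.05
    custom: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "one_over_f", "custom"):
            raise ValueError(f"unknown common-signal kind {self.kind!r}")
        if self.kind == "flat" and self.level < 0:
            raise ValueError("flat common-signal level must be nonnegative")
        if self.kind == "one_over_f" and (self.k < 0 or self.omega0 <= 0):
            raise ValueError("one_over_f requires k >= 0 and omega0 > 0")
        if self.kind == "custom":
            c = np.asarray(self.custom, dtype=float)
            if c.ndim != 1 or np.any(c < 0):
                raise ValueError("custom power spectrum must be 1-D and nonnegative")
            object.__setattr__(self, "custom", c)

    def power(self, grid: FrequencyGrid) -> np.ndarray:
        """U(omega) U*(omega) evaluated on the grid."""
        if self.kind == "flat":
            return np.full(grid.n_points, float(self.level))
        if self.kind == "one_over_f":
            return self.k / (grid.omega + self.omega0)
        if self.custom.size != grid.n_points:
            raise ValueError("custom power spectrum length does not match grid")
        return self.custom.copy()

    def to_json(self) -> str:
        obj = {"kind": self.kind}
        if self.kind == "flat":
            obj["level"] = self.level
        elif self.kind == "one_over_f":
            obj.update(k=self.k, omega0=self.omega0)
        else:
            obj["custom"] = self.custom.tolist()
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "CommonSignalSpec":
        obj = json.loads(text)
        if "custom" in obj:
            obj["custom"] = np.asarray(obj["custom"], dtype=float)
        return cls(**obj)


def inject_common(Q: SpectralMatrix, u: CommonSignalSpec) -> SpectralMatrix:
    """Add an independent common signal to every channel of Q.

    Every entry of Q(omega) — auto- and cross-spectra alike — is incremented
    by the common power U(omega)U*(omega), because all cross-terms with the
    independent u vanish in expectation. The result stays Hermitian PSD
    (the increment is the PSD rank-one matrix U U* ones(m, m)).
    """
    uu = u.power(Q.grid)
    if uu.size != Q.grid.n_points:
        raise ValueError("common-signal grid length does not match Q")
    return SpectralMatrix(Q.grid, Q.values + uu[:, None, None])


def mean_neural_power(Q: SpectralMatrix) -> float:
    """Mean power of the neural signals across channels and frequencies.

    For a two-channel Q on the 0..Nyquist grid this is
    (1 / (2 n_grid)) * sum_omega (S_11 + S_22) — i.e. the grand mean of the
    auto-spectra — which is the level the canonical simulations assign to
    the flat common signal.
    """
    auto = Q.auto_spectra()
    return float(np.sum(auto) / (Q.n_channels * Q.grid.n_points))


def ncr_from_coherence(C: float | np.ndarray) -> float | np.ndarray:
    """Invert the coherence->NCR relation: NCR = 1/sqrt(C) - 1.

    Valid under the assumptions that the neural signals are independent at
    the evaluated frequency and the NCR is equal across the two channels.
    ``C`` must lie in (0, 1]; C -> 0 sends the NCR to infinity.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ValueError("coherence must be > 0 (NCR unbounded as C -> 0)")
    if np.any(C > 1 + 1e-12):
        raise ValueError("coherence must be <= 1")
    out = 1.0 / np.sqrt(np.minimum(C, 1.0)) - 1.0
    return float(out) if out.ndim == 0 else out


def coherence_from_ncr(ncr: float | np.ndarray) -> float | np.ndarray:
    """Coherence induced by a common signal at neural-to-common ratio NCR:
    C = 1 / (NCR + 1)^2, strictly decreasing, C(0) = 1."""
    ncr = np.asarray(ncr, dtype=float)
    if np.any(ncr < 0):
        raise ValueError("NCR must be nonnegative")
    out = 1.0 / (ncr + 1.0) ** 2
    return float(out) if out.ndim == 0 else out


def bipolar_derive(recording: "Recording") -> "Recording":
    """Difference adjacent channels: b_i(t) = y_i(t) - y_{i+1}(t).

    Any signal entering both electrodes identically cancels exactly. The
    n-channel input yields n-1 bipolar channels positioned at the midpoints
    of the contributing electrode pairs, so separations remain multiples of
    the array pitch.
    """
    from .pipeline import Recording

    if recording.n_channels < 2:
        raise ValueError("bipolar derivation requires at least 2 channels")
    samples = recording.samples[:, :-1] - recording.samples[:, 1:]
    return Recording(
        samples=samples,
        fs=recording.fs,
        layout=recording.layout.midpoints(),
        label="bipolar",
        n_epochs=recording.n_epochs,
        epoch_s=recording.epoch_s,
    )


def shared_bipolar_coherence(P_i: float, P_i1: float, P_i2: float) -> float:
    """High-frequency coherence of two bipolar channels sharing a unipolar
    channel, for independent neural signals with powers P_i, P_i1 (shared),
    P_i2:

        bC = P_i1^2 / ((P_i + P_i1) (P_i2 + P_i1)).

    Equals 0.25 when the three powers are equal (the shared channel acts as
    a common signal with NCR = 1) and never exceeds that bound when the
    flanking powers are merely unequal to each other.
    """
    if min(P_i, P_i1, P_i2) < 0:
        raise ValueError("powers must be nonnegative")
    den = (P_i + P_i1) * (P_i2 + P_i1)
    if den == 0.0:
        raise ZeroDivisionError("both bipolar channels have zero power")
    return float(P_i1**2 / den)
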