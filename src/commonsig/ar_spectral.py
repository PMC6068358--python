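"""Analytic spectral representation of bivariate autoregressive processes.

A stationary bivariate AR process

    y(t) = sum_{l>=1} A(l) y(t-l) + e(t),   cov(e) = noise_cov,

has transfer function H(omega) = A(omega)^{-1} with
A(omega) = I - sum_l A(l) exp(-i omega l), and spectral density matrix

    Q(omega) = H(omega) noise_cov H(omega)*.

Q is Hermitian positive semi-definite at every frequency; its diagonal holds
the auto-spectra and its off-diagonal the cross-spectrum. Everything in this
package — coherence, Granger causality, common-signal algebra — is derived
from Q, so this module is the analytic ground truth against which both the
non-parametric factorization engine and the empirical multitaper pipeline
are checked.

The canonical two-node test system used throughout is unidirectionally
connected (node 1 drives node 2):

    y1(t) = a y1(t-1) + e1(t)
    y2(t) = c y2(t-1) + d y1(t-1) + e2(t)

with a = 0.1, c = 0.4, d = 0.1 and unit, uncorrelated innovations, which
yields power spectra that decay with frequency, loosely like a biological
system.  Its "disconnected twin" keeps the identical auto-spectra but has
zero cross-spectrum at every frequency, so the two systems cannot be told
apart by power alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "ARModel",
    "TransferDecomposition",
    "SpectralMatrix",
    "ar_transfer_function",
    "ar_spectral_matrix",
    "scenario_model",
    "simulate_timeseries",
    "UnstableModelError",
]

#: Default number of grid points on [0, Nyquist].
DEFAULT_GRID_POINTS = 512

#: Companion-matrix spectral radius must stay below 1 minus this margin.
STABILITY_MARGIN = 1e-6

#: Default number of initial samples discarded when simulating.
DEFAULT_BURN_IN = 1000


class UnstableModelError(ValueError):
    """Raised when an AR model is not (numerically) stationary."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Monotone frequency axis from 0 to the Nyquist frequency inclusive.

    ``values`` are in Hz when ``fs`` (sampling rate, Hz) is given, otherwise
    in normalized radians on [0, pi].
    """

    values: np.ndarray
    fs: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("frequency grid must be a 1-D array with >= 2 points")
        if v[0] != 0.0:
            raise ValueError("frequency grid must start at 0")
        if np.any(np.diff(v) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        nyq = np.pi if self.fs is None else self.fs / 2.0
        if not np.isclose(v[-1], nyq, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"frequency grid must end at the Nyquist frequency ({nyq}), got {v[-1]}"
            )

    @classmethod
    def default(cls, n_points: int = DEFAULT_GRID_POINTS, fs: float | None = None) -> "FrequencyGrid":
        nyq = np.pi if fs is None else fs / 2.0
        return cls(np.linspace(0.0, nyq, n_points), fs=fs)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def omega(self) -> np.ndarray:
        """Grid in normalized radians [0, pi]."""
        if self.fs is None:
            return self.values
        return 2.0 * np.pi * self.values / self.fs

    def matches(self, other: "FrequencyGrid") -> bool:
        return self.n_points == other.n_points and np.allclose(self.omega, other.omega)


@dataclass(frozen=True)
class ARModel:
    """Bivariate (or univariate) AR model in lag-operator sign convention.

    ``coeffs`` has shape (p + 1, m, m): ``coeffs[0]`` is the identity and
    ``coeffs[l]`` for l >= 1 is the lag-l matrix of the operator polynomial
    Phi(L) with Phi(L) y(t) = e(t); i.e. the *negative* of the "natural"
    coefficients of y(t) = sum A(l) y(t-l) + e(t). Use :meth:`from_natural`
    to build a model from natural coefficients.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        s = np.asarray(self.noise_cov, dtype=float)
        if c.ndim != 3 or c.shape[1] != c.shape[2]:
            raise ValueError("coeffs must have shape (n_lags+1, m, m)")
        m = c.shape[1]
        if not np.allclose(c[0], np.eye(m)):
            raise ValueError("lag-0 coefficient matrix must be the identity")
        if s.shape != (m, m) or not np.allclose(s, s.T):
            raise ValueError("noise_cov must be a symmetric (m, m) matrix")
        if np.any(np.linalg.eigvalsh(s) < -1e-12 * max(1.0, np.trace(s))):
            raise ValueError("noise_cov must be positive semi-definite")
        object.__setattr__(self, "coeffs", c)
        object.__setattr__(self, "noise_cov", s)

    @classmethod
    def from_natural(cls, natural_coeffs: np.ndarray, noise_cov: np.ndarray) -> "ARModel":
        """Build from natural form y(t) = sum_l natural_coeffs[l-1] y(t-l) + e(t).

        ``natural_coeffs`` has shape (p, m, m) for lags 1..p.
        """
        a = np.atleast_3d(np.asarray(natural_coeffs, dtype=float))
        m = a.shape[1]
        coeffs = np.concatenate([np.eye(m)[None], -a], axis=0)
        return cls(coeffs, np.asarray(noise_cov, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0] - 1

    @property
    def natural_coeffs(self) -> np.ndarray:
        """Lag 1..p coefficients of y(t) = sum A(l) y(t-l) + e(t)."""
        return -self.coeffs[1:]

    def spectral_radius(self) -> float:
        """Spectral radius of the VAR companion matrix (< 1 iff stationary)."""
        p, m = self.order, self.n_channels
        if p == 0:
            return 0.0
        comp = np.zeros((m * p, m * p))
        comp[:m, :] = np.concatenate(list(self.natural_coeffs), axis=1)
        if p > 1:
            comp[m:, :-m] = np.eye(m * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self, margin: float = STABILITY_MARGIN) -> bool:
        return self.spectral_radius() < 1.0 - margin

    def require_stable(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0 - STABILITY_MARGIN:
            raise UnstableModelError(
                f"AR model companion spectral radius {rho:.6g} >= {1 - STABILITY_MARGIN}"
            )

    # -- JSON round trip -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "sign_convention": "lag_operator",
                "coeffs": self.coeffs.tolist(),
                "noise_cov": self.noise_cov.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ARModel":
        obj = json.loads(text)
        coeffs = np.asarray(obj["coeffs"], dtype=float)
        if obj.get("sign_convention", "lag_operator") == "natural":
            return cls.from_natural(coeffs, np.asarray(obj["noise_cov"], dtype=float))
        return cls(coeffs, np.asarray(obj["noise_cov"], dtype=float))


@dataclass(frozen=True)
class TransferDecomposition:
    """Transfer function H(omega) per frequency plus innovation covariance."""

    grid: FrequencyGrid
    H: np.ndarray  # (n_freq, m, m) complex
    noise_cov: np.ndarray  # (m, m)

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=complex)
        if H.ndim != 3 or H.shape[0] != self.grid.n_points or H.shape[1] != H.shape[2]:
            raise ValueError("H must have shape (n_freq, m, m) matching the grid")
        if not np.all(np.isfinite(H)):
            raise ValueError("H must be finite at every frequency")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "noise_cov", np.asarray(self.noise_cov, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.H.shape[1]

    def spectral_matrix(self) -> "SpectralMatrix":
        """Q(omega) = H(omega) Sigma H(omega)*."""
        Q = self.H @ self.noise_cov @ np.conj(np.swapaxes(self.H, 1, 2))
        return SpectralMatrix(self.grid, Q)


@dataclass(frozen=True)
class SpectralMatrix:
    """Hermitian cross-spectral density matrix Q(omega) on a frequency grid.

    ``values`` has shape (n_freq, m, m); diagonal entries are auto-spectra,
    off-diagonal entries cross-spectra.
    """

    grid: FrequencyGrid
    values: np.ndarray

    _PSD_RTOL = 1e-10

    def __post_init__(self) -> None:
        Q = np.asarray(self.values, dtype=complex)
        if Q.ndim != 3 or Q.shape[0] != self.grid.n_points or Q.shape[1] != Q.shape[2]:
            raise ValueError("values must have shape (n_freq, m, m) matching the grid")
        if not np.allclose(Q, np.conj(np.swapaxes(Q, 1, 2)), atol=1e-10 * _scale(Q)):
            raise ValueError("Q(omega) must be Hermitian at every frequency")
        if np.any(np.real(np.diagonal(Q, axis1=1, axis2=2)) < -1e-12 * _scale(Q)):
            raise ValueError("auto-spectra must be nonnegative")
        # symmetrize exactly so downstream eigen/det computations are clean
        object.__setattr__(self, "values", 0.5 * (Q + np.conj(np.swapaxes(Q, 1, 2))))

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def auto_spectra(self) -> np.ndarray:
        """Real auto-spectra, shape (n_freq, m)."""
        return np.real(np.diagonal(self.values, axis1=1, axis2=2))

    def is_psd(self, rtol: float = _PSD_RTOL) -> bool:
        eig = np.linalg.eigvalsh(self.values)
        tr = np.real(np.trace(self.values, axis1=1, axis2=2))[:, None]
        return bool(np.all(eig >= -rtol * np.maximum(tr, 1e-300) - 1e-300))

    def to_table(self):
        """Long-format table: frequency, i, j, real, imag."""
        import pandas as pd

        n, m, _ = self.values.shape
        ii, jj = np.meshgrid(range(m), range(m), indexing="ij")
        rows = {
            "frequency": np.repeat(self.grid.values, m * m),
            "i": np.tile(ii.ravel(), n),
            "j": np.tile(jj.ravel(), n),
            "real": np.real(self.values).reshape(n, -1).ravel(),
            "imag": np.imag(self.values).reshape(n, -1).ravel(),
        }
        return pd.DataFrame(rows)

    @classmethod
    def from_table(cls, table, fs: float | None = None) -> "SpectralMatrix":
        freqs = np.unique(table["frequency"].to_numpy())
        m = int(table["i"].max()) + 1
        Q = np.zeros((freqs.size, m, m), dtype=complex)
        fidx = {f: k for k, f in enumerate(freqs)}
        for row in table.itertuples(index=False):
            Q[fidx[row.frequency], int(row.i), int(row.j)] = row.real + 1j * row.imag
        return cls(FrequencyGrid(freqs, fs=fs), Q)


def _scale(Q: np.ndarray) -> float:
    return float(np.max(np.abs(Q))) or 1.0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def ar_transfer_function(model: ARModel, grid: FrequencyGrid) -> TransferDecomposition:
    """Invert the AR operator polynomial on the grid: H(omega) = A(omega)^{-1}.

    A(omega) = sum_l coeffs[l] exp(-i omega l). Raises
    :class:`UnstableModelError` naming the first frequency where A(omega) is
    numerically singular.
    """
    omega = grid.omega
    lags = np.arange(model.coeffs.shape[0])
    # (n_freq, n_lags) phase factors contracted against (n_lags, m, m)
    phase = np.exp(-1j * np.outer(omega, lags))
    A = np.einsum("fl,lij->fij", phase, model.coeffs)
    det = np.linalg.det(A)
    bad = np.abs(det) < 1e-12
    if np.any(bad):
        f_bad = grid.values[np.argmax(bad)]
        raise UnstableModelError(
            f"AR operator A(omega) numerically singular at frequency {f_bad:.6g}"
        )
    H = np.linalg.inv(A)
    return TransferDecomposition(grid, H, model.noise_cov)


def ar_spectral_matrix(model: ARModel, grid: FrequencyGrid) -> SpectralMatrix:
    """Analytic spectral density matrix Q(omega) = H Sigma H* of an AR model."""
    model.require_stable()
    return ar_transfer_function(model, grid).spectral_matrix()


# -- canonical two-node simulation scenarios --------------------------------

#: AR parameters of the unidirectionally-connected reference system.
SCENARIO_A, SCENARIO_C, SCENARIO_D = 0.1, 0.4, 0.1


def connected_model(a: float = SCENARIO_A, c: float = SCENARIO_C, d: float = SCENARIO_D) -> ARModel:
    """Unidirectionally-connected system: node 1 drives node 2 with weight d."""
    natural = np.array([[[a, 0.0], [d, c]]])
    return ARModel.from_natural(natural, np.eye(2))


def scenario_model(which: str, grid: FrequencyGrid | None = None):
    """Return the canonical connected or disconnected two-node system.

    ``"connected"`` returns the :class:`ARModel` (a=0.1, c=0.4, d=0.1, unit
    uncorrelated noise). ``"disconnected"`` returns a :class:`SpectralMatrix`
    with exactly the connected system's auto-spectra but zero cross-spectrum
    — the two systems are indistinguishable by power alone.
    """
    if which == "connected":
        return connected_model()
    if which == "disconnected":
        grid = grid if grid is not None else FrequencyGrid.default()
        Q = ar_spectral_matrix(connected_model(), grid).values.copy()
        Q[:, 0, 1] = 0.0
        Q[:, 1, 0] = 0.0
        return SpectralMatrix(grid, Q)
    raise ValueError(f"unknown scenario {which!r}; expected 'connected' or 'disconnected'")


def simulate_timeseries(
    model: ARModel,
    n_samples: int,
    seed: int | np.random.Generator,
    burn_in: int = DEFAULT_BURN_IN,
) -> np.ndarray:
    """Simulate a realization of the AR process with Gaussian innovations.

    Returns an (n_samples, m) array. Deterministic given the seed; the first
    ``burn_in`` samples are generated and discarded so the output is (close
    to) stationary.
    """
    model.require_stable()
    p, m = model.order, model.n_channels
    if n_samples < 10 * max(p, 1):
        raise ValueError("n_samples must be at least 10x the maximum lag")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = n_samples + burn_in
    chol = np.linalg.cholesky(
        model.noise_cov + 1e-15 * np.trace(model.noise_cov) * np.eye(m)
    )
    innov = rng.standard_normal((total, m)) @ chol.T
    A = model.natural_coeffs  # (p, m, m)
    y = np.zeros((total, m))
    for t in range(total):
        acc = innov[t].copy()
        for l in range(1, min(p, t) + 1):
            acc += A[l - 1] @ y[t - l]
        y[t] = acc
    return y[burn_in:]
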