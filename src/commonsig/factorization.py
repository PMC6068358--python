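"""Wilson factorization of a spectral density matrix.

Non-parametric spectral Granger causality needs the factorization

    Q(omega) = H(omega) Sigma H(omega)*

with H minimum-phase (causal, normalized so its zero-lag coefficient is the
identity) and Sigma the innovation covariance — i.e. exactly the quantities
an AR fit would provide, obtained directly from Q without choosing a model
order.  This module implements Wilson's iterative algorithm:

  1. mirror Q from [0, Nyquist] onto the full frequency circle using
     Hermitian symmetry, Q(-omega) = Q(omega)^T;
  2. initialize psi(omega) with the symmetric PSD square root of the
     frequency-averaged Q;
  3. iterate psi <- psi [psi^{-1} Q psi^{-*} + I]_+ where [.]_+ keeps the
     causal part of the Fourier series (half of lag zero, upper triangle of
     lag zero removed to pin the unitary freedom);
  4. on convergence split psi(omega) = H(omega) A0 with A0 the zero-lag
     coefficient, giving Sigma = A0 A0^T.

Convergence is declared when the innovation covariance changes by less than
``tol`` (relative Frobenius norm) between iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import sqrtm

from .ar_spectral import FrequencyGrid, SpectralMatrix, TransferDecomposition

__all__ = [
    "wilson_factorize",
    "factorization_residual",
    "FactorizationError",
]

#: Relative eigenvalue jitter added to a (numerically) degenerate Q.
_JITTER = 1e-10


class FactorizationError(RuntimeError):
    """Raised when the Wilson iteration fails to converge; carries the last
    relative change and residual for diagnosis."""

    def __init__(self, message: str, last_delta: float, residual: float):
        super().__init__(message)
        self.last_delta = last_delta
        self.residual = residual


def _mirror_to_circle(Q: np.ndarray) -> np.ndarray:
    """Extend Q on [0, Nyquist] (n points) to the full circle (2(n-1) points).

    Index k = 0..n-1 holds omega_k; indices n..2n-3 hold the negative
    frequencies with Q(-omega) = conj(Q(omega)) = Q(omega)^T.
    """
    tail = np.conj(Q[-2:0:-1])  # omega in (Nyquist, 2pi) == negative freqs
    return np.concatenate([Q, tail], axis=0)


def _causal_part(g: np.ndarray) -> np.ndarray:
    """The [.]_+ operator on a matrix function sampled on the circle.

    Splits g = [g]_+ + [g]_+^H using the Fourier series: positive lags are
    kept whole and the Hermitian lag-zero coefficient is split into half
    its diagonal plus its full strictly-lower triangle (the anti-Hermitian
    correction that pins the arbitrary unitary factor so the zero-lag
    factor of psi stays triangular).
    """
    n_circle = g.shape[0]
    beta = np.fft.ifft(g, axis=0)
    g0 = beta[0]
    beta[0] = np.tril(g0, k=-1) + 0.5 * np.diag(np.diagonal(g0))
    beta[(n_circle + 1) // 2:] = 0.0
    return np.fft.fft(beta, axis=0)


def wilson_factorize(
    Q: SpectralMatrix,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> TransferDecomposition:
    """Factorize Q(omega) into a minimum-phase transfer function and
    innovation covariance, Q = H Sigma H*.

    Q is given on [0, Nyquist]; it is mirrored to the full circle
    internally and the outputs are returned on the input grid. Raises
    :class:`FactorizationError` if the iteration does not converge within
    ``max_iter`` and ValueError if Q is not Hermitian PSD beyond a small
    jitter tolerance.
    """
    Qv = Q.values.copy()
    m = Q.n_channels
    eig = np.linalg.eigvalsh(Qv)
    tr = np.real(np.trace(Qv, axis1=1, axis2=2))
    scale = float(np.mean(tr)) / m or 1.0
    if np.any(eig < -1e-6 * scale):
        raise ValueError("Q is not positive semi-definite (beyond jitter tolerance)")
    if np.any(eig < _JITTER * scale):
        warnings.warn(
            "Q numerically degenerate at some frequencies; adding diagonal jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        Qv = Qv + (_JITTER * scale) * np.eye(m)

    Qc = _mirror_to_circle(Qv)
    H_circle, sigma, delta, converged = _factorize_circle(Qc, tol, max_iter)
    decomp = TransferDecomposition(Q.grid, H_circle[: Q.grid.n_points], sigma)
    if not converged:
        raise FactorizationError(
            f"Wilson iteration did not converge in {max_iter} iterations "
            f"(last relative change {delta:.3g})",
            last_delta=delta,
            residual=factorization_residual(Q, decomp),
        )
    return decomp


def _factorize_circle(
    Qc: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Run the Wilson iteration on a full-circle Q; returns
    (H on the circle, Sigma, last relative Sigma change, converged)."""
    m = Qc.shape[1]
    # init: symmetric PSD square root of the frequency-averaged Q
    Q_mean = np.real(Qc.mean(axis=0))
    psi0 = np.real(sqrtm(0.5 * (Q_mean + Q_mean.T)))
    psi = np.broadcast_to(psi0, Qc.shape).astype(complex).copy()

    eye = np.eye(m)
    sigma = sigma_prev = psi0 @ psi0.T
    A0 = psi0
    delta = np.inf
    converged = False
    for _ in range(max_iter):
        psi_prev = psi
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Qc @ np.conj(np.swapaxes(psi_inv, 1, 2)) + eye
        psi = psi @ _causal_part(g)
        A0 = np.real(np.fft.ifft(psi, axis=0)[0])
        sigma = A0 @ A0.T
        # Sigma alone is invariant under the very first update from the
        # symmetric-sqrt init, so track the change in psi as well.
        delta_sigma = float(
            np.linalg.norm(sigma - sigma_prev) / max(np.linalg.norm(sigma), 1e-300)
        )
        delta_psi = float(
            np.max(np.abs(psi - psi_prev)) / max(np.max(np.abs(psi)), 1e-300)
        )
        delta = max(delta_sigma, delta_psi)
        sigma_prev = sigma
        if delta < tol:
            converged = True
            break
    return psi @ np.linalg.inv(A0), sigma, delta, converged


def factorization_residual(Q: SpectralMatrix, decomp: TransferDecomposition) -> float:
    """max over frequency of ||H Sigma H* - Q||_F relative to the overall
    scale of Q (max Frobenius norm across frequencies)."""
    if not Q.grid.matches(decomp.grid):
        raise ValueError("Q and decomposition grids do not match")
    recon = decomp.spectral_matrix().values
    err = np.linalg.norm(recon - Q.values, axis=(1, 2))
    scale = float(np.max(np.linalg.norm(Q.values, axis=(1, 2))))
    return float(np.max(err) / max(scale, 1e-300))
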