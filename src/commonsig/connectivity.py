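"""Coherence, spectral Granger causality, and their decomposition.

For a pair of channels with spectral density matrix Q(omega) (auto-spectra
S_ii, S_jj; cross-spectrum S_ij) and factorization Q = H Sigma H* with
Sigma = [[S, g], [g, G]]:

  coherence            C(omega)      = |S_ij|^2 / (S_ii S_jj)
  total interdependence f_{i,j}      = -ln(1 - C)
  GC i -> j            f_{i->j}      = ln( S_jj / (Ht_jj G Ht_jj*) )
  GC i <- j            f_{i<-j}      = ln( S_ii / (Ht_ii S Ht_ii*) )
  instantaneous        f_{i.j}       = ln( (Ht_ii S Ht_ii*)(Ht_jj G Ht_jj*) / det Q )
  total GC             f_{i<->j}     = f_{i->j} + f_{i<-j}

where the corrected transfer entries Ht_jj = H_jj + (g/G) H_ij and
Ht_ii = H_ii + (g/S) H_ji remove the influence of correlated innovations
(they reduce to H_jj, H_ii when g = 0; the correction is applied
unconditionally here).  These quantities satisfy the identity

  -ln(1 - C) = f_{i->j} + f_{i<-j} + f_{i.j}

at every frequency: a transform of coherence splits exactly into lagged
(Granger) and instantaneous terms.  Common signals inflate the
instantaneous term — for a disconnected pair contaminated by a shared
signal essentially *all* of the transformed coherence is instantaneous —
which is what makes the decomposition a diagnostic.  The directional terms
are nonnegative for PSD inputs; the instantaneous term can go (slightly)
negative, which is reported as-is and flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ar_spectral import FrequencyGrid, SpectralMatrix, TransferDecomposition
from .factorization import factorization_residual

__all__ = [
    "ConnectivitySpectra",
    "coherence",
    "transform_coherence",
    "granger_decompose",
    "pct_instantaneous",
]

#: Default ceiling on the acceptable relative factorization residual of the
#: decomposition passed to :func:`granger_decompose`.
DEFAULT_RESIDUAL_TOL = 1e-3

#: |f_{i,j}| below this is treated as exactly zero when forming the
#: instantaneous percentage (the ratio is then undefined, encoded as NaN).
PCT_UNDEFINED_ATOL = 1e-12


@dataclass(frozen=True)
class ConnectivitySpectra:
    """Per-frequency connectivity measures for one channel pair.

    ``pct_instantaneous`` is NaN wherever the transformed coherence is zero
    (the percentage is undefined there, not fabricated).
    ``has_negative_instantaneous`` flags spectra where numerical
    imperfection (or genuine model violation) drove f_{i.j} below zero.
    """

    grid: FrequencyGrid
    coherence: np.ndarray
    transformed_coherence: np.ndarray
    gc_forward: np.ndarray  # f_{i->j}
    gc_backward: np.ndarray  # f_{i<-j}
    instantaneous: np.ndarray  # f_{i.j}
    decomposition_residual: float = 0.0

    @property
    def total_gc(self) -> np.ndarray:
        """f_{i<->j} = f_{i->j} + f_{i<-j}."""
        return self.gc_forward + self.gc_backward

    @property
    def pct_instantaneous(self) -> np.ndarray:
        return pct_instantaneous(self)

    @property
    def has_negative_instantaneous(self) -> bool:
        return bool(np.any(self.instantaneous < 0))

    def to_table(self):
        """Long-format table: frequency, metric, value."""
        import pandas as pd

        metrics = {
            "coherence": self.coherence,
            "transformed_coherence": self.transformed_coherence,
            "gc_forward": self.gc_forward,
            "gc_backward": self.gc_backward,
            "total_gc": self.total_gc,
            "instantaneous": self.instantaneous,
            "pct_instantaneous": self.pct_instantaneous,
        }
        frames = [
            pd.DataFrame(
                {"frequency": self.grid.values, "metric": name, "value": vals}
            )
            for name, vals in metrics.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def band_summary(self, bands: dict[str, tuple[float, float]]) -> dict:
        """Band-averaged metrics, JSON-serializable. Bands are (lo, hi) in
        the grid's frequency units, inclusive."""
        out: dict[str, dict[str, float | None]] = {}
        for name, (lo, hi) in bands.items():
            mask = (self.grid.values >= lo) & (self.grid.values <= hi)
            if not np.any(mask):
                raise ValueError(f"band {name!r} = ({lo}, {hi}) contains no grid points")
            pct = self.pct_instantaneous[mask]
            pct_mean = float(np.nanmean(pct)) if np.any(np.isfinite(pct)) else None
            out[name] = {
                "coherence": float(np.mean(self.coherence[mask])),
                "transformed_coherence": float(np.mean(self.transformed_coherence[mask])),
                "total_gc": float(np.mean(self.total_gc[mask])),
                "instantaneous": float(np.mean(self.instantaneous[mask])),
                "pct_instantaneous": pct_mean,
            }
        return out


def coherence(Q: SpectralMatrix) -> np.ndarray:
    """C(omega) = |S_ij(omega)|^2 / (S_ii(omega) S_jj(omega)) in [0, 1]."""
    auto = Q.auto_spectra()
    if np.any(auto <= 0):
        raise ValueError("coherence requires strictly positive auto-spectra")
    num = np.abs(Q.values[:, 0, 1]) ** 2
    C = num / (auto[:, 0] * auto[:, 1])
    if np.any(C > 1 + 1e-12):
        raise ValueError("coherence exceeded 1 beyond numerical slack; Q invalid")
    return np.clip(C, 0.0, 1.0)


def transform_coherence(C: np.ndarray, cap: float | None = None) -> np.ndarray:
    """Total interdependence -ln(1 - C): 0 at C = 0, unbounded as C -> 1.

    C = 1 exactly is an error unless ``cap`` is given, in which case such
    points map to ``cap`` (useful for synthetic rank-deficient inputs).
    """
    C = np.asarray(C, dtype=float)
    if np.any((C < 0) | (C > 1)):
        raise ValueError("coherence must lie in [0, 1]")
    at_one = C >= 1.0
    if np.any(at_one):
        if cap is None:
            raise ValueError(
                "coherence of exactly 1 makes -ln(1-C) unbounded; pass cap= to map it"
            )
        out = np.empty_like(C)
        out[~at_one] = -np.log1p(-C[~at_one])
        out[at_one] = cap
        return out
    return -np.log1p(-C)


def granger_decompose(
    Q: SpectralMatrix,
    decomp: TransferDecomposition,
    residual_tol: float = DEFAULT_RESIDUAL_TOL,
) -> ConnectivitySpectra:
    """Compute the full coherence/GC/instantaneous decomposition for a
    two-channel Q and its factorization.

    ``decomp`` must actually factorize Q: if the relative residual
    ||H Sigma H* - Q|| exceeds ``residual_tol`` the call is refused with a
    diagnostic.  The instantaneous term is computed directly from its
    closed form (not as the identity residual); the residual of the
    identity -ln(1-C) = f_fwd + f_bwd + f_inst is recorded on the result as
    a cross-check.
    """
    if Q.n_channels != 2:
        raise ValueError("granger_decompose is defined for channel pairs (2x2 Q)")
    if not Q.grid.matches(decomp.grid):
        raise ValueError("Q and decomposition grids do not match")
    resid = factorization_residual(Q, decomp)
    if resid > residual_tol:
        raise ValueError(
            f"decomposition does not factorize Q: relative residual {resid:.3g} "
            f"> tolerance {residual_tol:.3g}; refusing to derive GC from it"
        )

    S = float(decomp.noise_cov[0, 0])
    G = float(decomp.noise_cov[1, 1])
    g = float(decomp.noise_cov[0, 1])
    H = decomp.H
    # corrected transfer entries (no-op when innovations are uncorrelated):
    # orthogonalizing the innovations (e_j minus its projection on e_i and
    # vice versa) folds the cross-transfer into the own-channel entry
    Ht_ii = H[:, 0, 0] + (g / S) * H[:, 0, 1]
    Ht_jj = H[:, 1, 1] + (g / G) * H[:, 1, 0]

    auto = Q.auto_spectra()
    S_ii, S_jj = auto[:, 0], auto[:, 1]
    C = coherence(Q)
    f_total = transform_coherence(C)

    own_j = np.real(Ht_jj * np.conj(Ht_jj)) * G
    own_i = np.real(Ht_ii * np.conj(Ht_ii)) * S
    with np.errstate(divide="raise", invalid="raise"):
        f_fwd = np.log(S_jj / own_j)
        f_bwd = np.log(S_ii / own_i)
        detQ = np.real(np.linalg.det(Q.values))
        f_inst = np.log(own_i * own_j / detQ)

    identity_resid = float(np.max(np.abs(f_total - f_fwd - f_bwd - f_inst)))
    return ConnectivitySpectra(
        grid=Q.grid,
        coherence=C,
        transformed_coherence=f_total,
        gc_forward=f_fwd,
        gc_backward=f_bwd,
        instantaneous=f_inst,
        decomposition_residual=identity_resid,
    )


def pct_instantaneous(
    spectra: ConnectivitySpectra, atol: float = PCT_UNDEFINED_ATOL
) -> np.ndarray:
    """100 * f_{i.j} / f_{i,j}; NaN (undefined) where f_{i,j} is zero.

    For a genuinely disconnected, uncontaminated pair the transformed
    coherence vanishes everywhere and the percentage is undefined at every
    frequency — that is reported honestly rather than as 0 or 100.
    """
    f_total = spectra.transformed_coherence
    out = np.full_like(f_total, np.nan)
    defined = np.abs(f_total) > atol
    out[defined] = 100.0 * spectra.instantaneous[defined] / f_total[defined]
    return out
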