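"""Coherence, spectral GC, instantaneous interaction and the
decomposition identity."""

import numpy as np
import pytest

from commonsig.ar_spectral import (
    ARModel,
    FrequencyGrid,
    SpectralMatrix,
    ar_spectral_matrix,
    ar_transfer_function,
)
from commonsig.connectivity import (
    coherence,
    granger_decompose,
    pct_instantaneous,
    transform_coherence,
)
from commonsig.factorization import wilson_factorize
from commonsig.synthetic import scenario_spectral_matrix


def _const_Q(grid, mat):
    return SpectralMatrix(
        grid, np.broadcast_to(np.asarray(mat, complex), (grid.n_points, 2, 2)).copy()
    )


class TestCoherence:
    def test_diagonal_q_is_zero(self, grid):
        assert np.allclose(coherence(_const_Q(grid, np.diag([1.0, 2.0]))), 0.0)

    def test_ncr_one_matrix_gives_quarter(self, grid):
        assert np.allclose(coherence(_const_Q(grid, [[2.0, 1.0], [1.0, 2.0]])), 0.25)

    def test_rank_one_q_gives_unity(self, grid):
        Q = _const_Q(grid, [[4.0, 2.0], [2.0, 1.0]])
        assert np.allclose(coherence(Q), 1.0)

    def test_zero_autospectrum_rejected(self, grid):
        with pytest.raises(ValueError):
            coherence(_const_Q(grid, np.diag([0.0, 1.0])))


class TestTransformCoherence:
    def test_range_anchors(self):
        assert transform_coherence(np.array([0.01]))[0] == pytest.approx(0.0101, abs=5e-5)
        assert transform_coherence(np.array([0.99]))[0] == pytest.approx(4.6052, abs=5e-5)
        assert transform_coherence(np.array([0.0]))[0] == 0.0

    def test_unit_coherence_requires_cap(self):
        with pytest.raises(ValueError):
            transform_coherence(np.array([1.0]))
        assert transform_coherence(np.array([1.0]), cap=30.0)[0] == 30.0

    def test_monotone(self):
        c = np.linspace(0, 0.999, 200)
        assert np.all(np.diff(transform_coherence(c)) > 0)


class TestGrangerDecompose:
    def test_scenario1_structure(self, grid):
        """One-way coupling: no backward GC, no instantaneous term, forward
        GC matching the closed form ln(1 + d^2/|1-a|^2) at zero frequency."""
        Q = scenario_spectral_matrix(1, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        assert np.allclose(s.gc_backward, 0.0, atol=1e-8)
        assert np.allclose(s.instantaneous, 0.0, atol=1e-8)
        assert s.gc_forward[0] == pytest.approx(np.log(1 + 0.01 / 0.81), abs=1e-6)
        assert s.gc_forward[0] == pytest.approx(0.01227, abs=1e-5)

    def test_disconnected_all_zero(self, grid):
        Q = scenario_spectral_matrix(2, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        for arr in (s.coherence, s.gc_forward, s.gc_backward, s.instantaneous):
            assert np.allclose(arr, 0.0, atol=1e-7)

    def test_decomposition_identity_for_battery(self, ar_battery, grid):
        """-ln(1-C) = f_fwd + f_bwd + f_inst at every frequency, parametric
        and non-parametric routes agreeing pointwise."""
        for model in ar_battery:
            Q = ar_spectral_matrix(model, grid)
            nonparam = granger_decompose(Q, wilson_factorize(Q))
            assert nonparam.decomposition_residual < 1e-6
            param = granger_decompose(Q, ar_transfer_function(model, grid))
            assert param.decomposition_residual < 1e-10
            for attr in ("gc_forward", "gc_backward", "instantaneous"):
                assert np.allclose(
                    getattr(nonparam, attr), getattr(param, attr), atol=1e-4
                ), attr

    def test_directional_gc_nonnegative_with_correlated_noise(self, ar_battery, grid):
        for model in ar_battery:
            Q = ar_spectral_matrix(model, grid)
            s = granger_decompose(Q, wilson_factorize(Q))
            assert np.all(s.gc_forward >= -1e-9)
            assert np.all(s.gc_backward >= -1e-9)

    def test_scalar_multiplication_invariance(self, connected, grid):
        """Rescaling one channel leaves coherence and every GC spectrum
        unchanged (Geweke invariance)."""
        Q = ar_spectral_matrix(connected, grid)
        D = np.diag([3.0, 1.0])
        Qs = SpectralMatrix(grid, D @ Q.values @ D)
        a = granger_decompose(Q, wilson_factorize(Q))
        b = granger_decompose(Qs, wilson_factorize(Qs))
        for attr in ("coherence", "gc_forward", "gc_backward", "instantaneous"):
            assert np.allclose(getattr(a, attr), getattr(b, attr), atol=1e-8), attr

    def test_common_signal_reduces_total_gc(self, grid):
        s1 = granger_decompose(
            scenario_spectral_matrix(1, grid),
            wilson_factorize(scenario_spectral_matrix(1, grid)),
        )
        s3 = granger_decompose(
            scenario_spectral_matrix(3, grid),
            wilson_factorize(scenario_spectral_matrix(3, grid)),
        )
        assert np.all(s3.total_gc < s1.total_gc)

    def test_bad_factorization_refused(self, connected, grid):
        from commonsig.ar_spectral import TransferDecomposition

        Q = ar_spectral_matrix(connected, grid)
        wrong = TransferDecomposition(
            grid, np.broadcast_to(np.eye(2), Q.values.shape).astype(complex), np.eye(2)
        )
        with pytest.raises(ValueError, match="does not factorize"):
            granger_decompose(Q, wrong)

    def test_grid_mismatch_refused(self, connected, grid):
        Q = ar_spectral_matrix(connected, grid)
        other = ar_transfer_function(connected, FrequencyGrid.default(64))
        with pytest.raises(ValueError, match="grids"):
            granger_decompose(Q, other)


class TestPctInstantaneous:
    def test_scenario1_zero_where_defined(self, grid):
        Q = scenario_spectral_matrix(1, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        pct = pct_instantaneous(s, atol=1e-8)
        assert np.all(np.isfinite(pct))
        assert np.allclose(pct, 0.0, atol=1e-3)

    def test_disconnected_undefined_everywhere(self, grid):
        Q = scenario_spectral_matrix(2, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        assert np.all(np.isnan(pct_instantaneous(s)))

    def test_scenario4_near_total(self, grid):
        Q = scenario_spectral_matrix(4, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        pct = pct_instantaneous(s)
        assert np.nanmin(pct) > 80.0
        assert np.nanmax(pct) <= 100.0 + 1e-6


class TestTablesAndSummaries:
    def test_long_format_table(self, grid):
        Q = scenario_spectral_matrix(1, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        table = s.to_table()
        assert set(table.columns) == {"frequency", "metric", "value"}
        assert set(table["metric"]) == {
            "coherence",
            "transformed_coherence",
            "gc_forward",
            "gc_backward",
            "total_gc",
            "instantaneous",
            "pct_instantaneous",
        }

    def test_band_summary_json_roundtrip(self, grid):
        import json

        Q = scenario_spectral_matrix(1, grid)
        s = granger_decompose(Q, wilson_factorize(Q))
        out = s.band_summary({"low": (0.0, 1.0), "high": (2.0, np.pi)})
        assert json.loads(json.dumps(out)) == out
        # the uncontaminated connected system's coherence decays with frequency
        assert out["low"]["coherence"] > out["high"]["coherence"]
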