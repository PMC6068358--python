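"""Common-signal algebra: injection, NCR relations, bipolar derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commonsig.ar_spectral import (
    FrequencyGrid,
    SpectralMatrix,
    ar_spectral_matrix,
    connected_model,
)
from commonsig.common_signal import (
    ChannelLayout,
    CommonSignalSpec,
    bipolar_derive,
    coherence_from_ncr,
    inject_common,
    mean_neural_power,
    ncr_from_coherence,
    shared_bipolar_coherence,
)
from commonsig.connectivity import coherence
from commonsig.pipeline import Recording


def _const_Q(grid, mat):
    return SpectralMatrix(grid, np.broadcast_to(np.asarray(mat, complex), (grid.n_points, 2, 2)).copy())


class TestInjectCommon:
    def test_identity_plus_unit_flat_gives_quarter_coherence(self, grid):
        Qc = inject_common(_const_Q(grid, np.eye(2)), CommonSignalSpec("flat", level=1.0))
        assert np.allclose(Qc.values, [[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(coherence(Qc), 0.25)

    def test_zero_common_signal_is_noop(self, grid, connected):
        Q = ar_spectral_matrix(connected, grid)
        Qc = inject_common(Q, CommonSignalSpec("flat", level=0.0))
        assert np.array_equal(Qc.values, Q.values)

    def test_power_increment_equals_common_power(self, grid, connected):
        Q = ar_spectral_matrix(connected, grid)
        u = CommonSignalSpec("one_over_f", k=0.5, omega0=0.05)
        Qc = inject_common(Q, u)
        assert np.allclose(Qc.auto_spectra() - Q.auto_spectra(), u.power(grid)[:, None])
        assert Qc.is_psd()

    def test_matches_direct_coherence_formula(self, grid):
        """Coherence after injection equals the closed form
        |Sxy + UU*|^2 / ((Sxx + UU*)(Syy + UU*)) exactly."""
        Qd = ar_spectral_matrix(connected_model(), grid).values.copy()
        Qd[:, 0, 1] = 0
        Qd[:, 1, 0] = 0
        Q = SpectralMatrix(grid, Qd)
        u = CommonSignalSpec("flat", level=0.7)
        got = coherence(inject_common(Q, u))
        uu = u.power(grid)
        s = Q.auto_spectra()
        expected = uu**2 / ((s[:, 0] + uu) * (s[:, 1] + uu))
        assert np.allclose(got, expected, atol=1e-12)

    def test_grid_mismatch_rejected(self, grid):
        u = CommonSignalSpec("custom", custom=np.ones(7))
        with pytest.raises(ValueError):
            inject_common(_const_Q(grid, np.eye(2)), u)


class TestMeanNeuralPower:
    def test_identity_gives_one(self, grid):
        assert mean_neural_power(_const_Q(grid, np.eye(2))) == 1.0

    def test_constant_spectra_average(self, grid):
        assert mean_neural_power(_const_Q(grid, np.diag([2.0, 4.0]))) == pytest.approx(3.0)

    def test_connected_matches_time_domain_variances(self, grid, connected):
        from commonsig.ar_spectral import simulate_timeseries

        mp = mean_neural_power(ar_spectral_matrix(connected, grid))
        y = simulate_timeseries(connected, 200_000, seed=2)
        assert mp == pytest.approx(y.var(axis=0).mean(), rel=0.02)


class TestNCRRelations:
    def test_paper_anchor_values(self):
        assert ncr_from_coherence(0.5) == pytest.approx(0.41, abs=0.005)
        assert ncr_from_coherence(1.0) == 0.0
        assert ncr_from_coherence(0.25) == pytest.approx(1.0)
        assert coherence_from_ncr(1.0) == pytest.approx(0.25)
        assert coherence_from_ncr(0.0) == 1.0

    @pytest.mark.parametrize("x", [0.1, 0.41, 2.0])
    def test_round_trip(self, x):
        assert ncr_from_coherence(coherence_from_ncr(x)) == pytest.approx(x)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ncr_from_coherence(0.0)
        with pytest.raises(ValueError):
            ncr_from_coherence(1.5)
        with pytest.raises(ValueError):
            coherence_from_ncr(-0.1)

    def test_monotone_decreasing(self):
        ncr = np.linspace(0.0, 5.0, 100)
        c = coherence_from_ncr(ncr)
        assert np.all(np.diff(c) < 0)
        back = ncr_from_coherence(np.linspace(0.01, 1.0, 100))
        assert np.all(np.diff(back) < 0)


def _recording(samples, positions):
    samples = np.asarray(samples, dtype=float)
    return Recording(
        samples=samples,
        fs=1000.0,
        layout=ChannelLayout(np.asarray(positions, float)),
        n_epochs=1,
        epoch_s=samples.shape[0] / 1000.0,
    )


class TestBipolarDerive:
    def test_common_offset_cancels(self):
        n = 100
        x = np.column_stack([np.full(n, 3.0), np.full(n, 1.0)])
        u = 5.0
        rec = _recording(x - u + 0.001 * np.arange(n)[:, None] * 0, [0.0, 25.0])
        out = bipolar_derive(rec)
        assert np.allclose(out.samples, 2.0)

    def test_identical_channels_cancel_bitwise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        rec = _recording(np.column_stack([x, x, x]), [0.0, 25.0, 50.0])
        out = bipolar_derive(rec)
        assert np.all(out.samples == 0.0)

    def test_output_independent_of_common_signal(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((300, 4))
        u1 = rng.standard_normal(300)
        u2 = 10.0 * rng.standard_normal(300)
        a = bipolar_derive(_recording(x - u1[:, None], np.arange(4) * 25.0))
        b = bipolar_derive(_recording(x - u2[:, None], np.arange(4) * 25.0))
        # identical up to floating-point cancellation error (exact algebraic
        # cancellation; bit-level identity would need exact arithmetic)
        assert np.allclose(a.samples, b.samples, atol=1e-12)
        clean = bipolar_derive(_recording(x, np.arange(4) * 25.0))
        assert np.allclose(a.samples, clean.samples, atol=1e-12)

    def test_positions_are_midpoints(self):
        rec = _recording(np.zeros((10, 3)) + np.arange(3), [0.0, 25.0, 50.0])
        out = bipolar_derive(rec)
        assert np.allclose(out.layout.positions, [12.5, 37.5])
        assert out.label == "bipolar"

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            bipolar_derive(_recording(np.ones((10, 1)), [0.0]))


class TestSharedBipolarCoherence:
    def test_equal_powers_give_quarter(self):
        assert shared_bipolar_coherence(1.0, 1.0, 1.0) == pytest.approx(0.25)

    def test_edge_cases(self):
        assert shared_bipolar_coherence(1.0, 0.0, 1.0) == 0.0
        assert shared_bipolar_coherence(0.0, 1.0, 0.0) == 1.0
        with pytest.raises(ZeroDivisionError):
            shared_bipolar_coherence(0.0, 0.0, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p_i=st.floats(1e-3, 1e3),
        p_shared=st.floats(1e-3, 1e3),
        p_j=st.floats(1e-3, 1e3),
    )
    def test_bounded_by_geometric_mean_ncr_law(self, p_i, p_shared, p_j):
        """The shared channel acts as a common signal: coherence never
        exceeds 1/(sqrt(NCR_i NCR_j) + 1)^2, the NCR law at the geometric
        mean of the flanking channels' NCRs, reaching it only at equal
        flanking powers; and never exceeds 0.25 when the shared power is at
        most the geometric mean of the flanking powers."""
        bc = shared_bipolar_coherence(p_i, p_shared, p_j)
        bound = coherence_from_ncr(np.sqrt((p_i / p_shared) * (p_j / p_shared)))
        assert bc <= bound + 1e-12
        if p_shared**2 <= p_i * p_j:
            assert bc <= 0.25 + 1e-12


class TestCommonSignalSpec:
    def test_json_round_trip(self):
        for spec in (
            CommonSignalSpec("flat", level=2.0),
            CommonSignalSpec("one_over_f", k=0.3, omega0=0.01),
            CommonSignalSpec("custom", custom=np.array([1.0, 2.0, 0.0])),
        ):
            clone = CommonSignalSpec.from_json(spec.to_json())
            g = FrequencyGrid(np.linspace(0, np.pi, 3))
            assert np.allclose(clone.power(g), spec.power(g))

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            CommonSignalSpec("flat", level=-1.0)
        with pytest.raises(ValueError):
            CommonSignalSpec("custom", custom=np.array([1.0, -0.5]))
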