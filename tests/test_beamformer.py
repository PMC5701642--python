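"""Beamformer-core tests: covariance, filters, orientation, outputs, scan."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beamcascade import (Covariance, DegenerateInputError, InversionError,
                         assemble_measurement, demean_channels, excess_kurtosis,
                         filter_weights, frobenius_normalize,
                         make_spike_waveform, optimal_orientation,
                         sample_covariance, scan, variance_output,
                         compute_leadfields, CONSTRAINTS)
from conftest import random_spd
from oracles import (covariance_double_loop, excess_kurtosis_direct,
                     grid_directions, orientation_objective)


class TestSampleCovariance:
    def test_single_channel_two_samples(self):
        c = sample_covariance(np.array([[1.0, -1.0]]))
        assert c.matrix == pytest.approx(np.array([[1.0]]))
        assert c.n_samples == 2

    def test_zero_data_gives_zero_matrix(self):
        assert not np.any(sample_covariance(np.zeros((4, 10))).matrix)

    def test_matches_double_loop_oracle(self, rng):
        b = rng.standard_normal((5, 40))
        b -= b.mean(axis=1, keepdims=True)
        c = sample_covariance(b)
        assert np.allclose(c.matrix, covariance_double_loop(b), atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sample_covariance(np.ones((3, 1)))

    def test_rank_deficient_without_loading_raises(self, rng):
        b = np.outer(rng.standard_normal(8), rng.standard_normal(100))
        cov = sample_covariance(b)
        with pytest.raises(InversionError, match="loading"):
            cov.solve(np.eye(8))
        loaded = sample_covariance(b, loading=0.05)
        assert np.all(np.isfinite(loaded.solve(np.eye(8))))


class TestFrobeniusNormalize:
    def test_unit_norm_and_identity_case(self):
        g = frobenius_normalize(np.eye(3))
        assert np.linalg.norm(g) == pytest.approx(1.0)
        assert np.allclose(np.diag(g), 1.0 / np.sqrt(3.0))

    def test_idempotent(self, rng):
        g = rng.standard_normal((10, 3))
        once = frobenius_normalize(g)
        assert np.allclose(frobenius_normalize(once), once, rtol=1e-15)

    def test_zero_gain_rejected(self):
        with pytest.raises(DegenerateInputError):
            frobenius_normalize(np.zeros((4, 3)))


class TestFilterIdentities:
    """Constraint identities and the scaling relations between the filters."""

    def _instance(self, rng, n=12):
        L = rng.standard_normal(n)
        C = Covariance(matrix=random_spd(rng, n), n_samples=1000)
        return L, C

    def test_identity_covariance_closed_form(self, rng):
        L = rng.standard_normal(10)
        C = Covariance(matrix=np.eye(10), n_samples=100)
        w = filter_weights(L, C, "unit_gain")
        assert np.allclose(w, L / (L @ L), rtol=1e-12)
        assert w @ L == pytest.approx(1.0)

    @pytest.mark.parametrize("constraint", CONSTRAINTS)
    def test_constraint_identity(self, rng, constraint):
        L, C = self._instance(rng)
        w = filter_weights(L, C, constraint)
        if constraint == "unit_gain":
            assert w @ L == pytest.approx(1.0, rel=1e-8)
        elif constraint == "unit_array_gain":
            assert w @ L == pytest.approx(np.linalg.norm(L), rel=1e-8)
        else:
            assert w @ w == pytest.approx(1.0, rel=1e-8)
            assert w @ L > 0

    def test_scaling_relations_between_filters(self, rng):
        L, C = self._instance(rng)
        wug = filter_weights(L, C, "unit_gain")
        wuag = filter_weights(L, C, "unit_array_gain")
        wung = filter_weights(L, C, "unit_noise_gain")
        assert np.allclose(wuag, np.linalg.norm(L) * wug, rtol=1e-8)
        assert np.allclose(wung, wug / np.linalg.norm(wug), rtol=1e-8)

    def test_kurtosis_invariant_across_filter_scalings(self, rng):
        # array-gain and noise-gain filters are scalar multiples of unit gain,
        # and excess kurtosis is invariant to scalar multiplication
        L, C = self._instance(rng, n=6)
        b = rng.standard_normal((6, 500))
        y1 = filter_weights(L, C, "unit_gain") @ b
        y2 = filter_weights(L, C, "unit_array_gain") @ b
        assert excess_kurtosis(y1) == pytest.approx(excess_kurtosis(y2), rel=1e-8)


class TestOptimalOrientation:
    @pytest.mark.parametrize("constraint", CONSTRAINTS)
    def test_beats_direction_grid_oracle(self, rng, constraint):
        dirs = grid_directions(4000)
        for _ in range(10):
            gain = rng.standard_normal((15, 3))
            C = Covariance(matrix=random_spd(rng, 15), n_samples=1000)
            u = optimal_orientation(gain, C, constraint)
            cinv = np.linalg.inv(C.matrix)
            best_grid = orientation_objective(gain, cinv, constraint, dirs).max()
            ours = orientation_objective(gain, cinv, constraint, u[None, :])[0]
            assert ours >= best_grid * (1.0 - 1e-6)

    def test_rank_one_gain_aligns_with_its_direction(self, rng):
        d = np.array([0.6, -0.8, 0.0])
        gain = np.outer(rng.standard_normal(10), d)
        C = Covariance(matrix=random_spd(rng, 10), n_samples=100)
        for constraint in CONSTRAINTS:
            u = optimal_orientation(gain, C, constraint)
            assert abs(u @ d) == pytest.approx(1.0, abs=1e-9)

    def test_identity_covariance_noise_gain_tie_break(self, rng):
        gain = rng.standard_normal((10, 3))
        C = Covariance(matrix=np.eye(10), n_samples=100)
        u = optimal_orientation(gain, C, "unit_noise_gain")
        _, _, vt = np.linalg.svd(gain)
        assert abs(u @ vt[0]) == pytest.approx(1.0, abs=1e-9)


class TestOutputs:
    def test_variance_equals_direct_time_series_variance(self, rng):
        b = rng.standard_normal((6, 2000))
        b -= b.mean(axis=1, keepdims=True)
        w = rng.standard_normal(6)
        direct = np.mean((w @ b) ** 2)
        assert variance_output(w, b) == pytest.approx(direct, rel=1e-10)

    def test_variance_scaling_and_orthogonality(self, rng):
        b = rng.standard_normal((4, 50))
        b -= b.mean(axis=1, keepdims=True)
        w = rng.standard_normal(4)
        assert variance_output(3.0 * w, b) == pytest.approx(9.0 * variance_output(w, b))
        q, _ = np.linalg.qr(b[:, :3])
        w_perp = np.eye(4)[:, 3] - q @ (q.T @ np.eye(4)[:, 3])
        b_rank3 = q @ (q.T @ b)
        assert variance_output(w_perp, b_rank3) == pytest.approx(0.0, abs=1e-12)


class TestExcessKurtosis:
    def test_alternating_signs_attain_lower_bound(self):
        assert excess_kurtosis(np.tile([1.0, -1.0], 50)) == pytest.approx(-2.0)

    def test_small_sample_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert excess_kurtosis(x) == pytest.approx(-1.3)
        assert excess_kurtosis(x) == pytest.approx(excess_kurtosis_direct(x))

    def test_gaussian_sample_is_near_zero(self):
        x = np.random.default_rng(42).standard_normal(10 ** 6)
        assert abs(excess_kurtosis(x)) < 0.02

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(-100, 100).filter(lambda v: abs(v) > 1e-6),
           b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(7).standard_normal(256)
        assert excess_kurtosis(a * x + b) == pytest.approx(excess_kurtosis(x),
                                                           rel=1e-9, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            excess_kurtosis(np.full(20, 3.3))
        with pytest.raises(ValueError):
            excess_kurtosis(np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def scan_setup(shells, eeg_sensors, source_space, reference_sources):
    lead = compute_leadfields(shells, eeg_sensors, source_space.node_positions)
    ref_gain = compute_leadfields(shells, eeg_sensors, reference_sources[:1])
    wf = make_spike_waveform()
    from beamcascade import add_white_noise, common_average_reference
    m = assemble_measurement(ref_gain.node_gain(0) @ np.array([0.0, 0.6, 0.8]),
                             wf, [200, 1800], duration_s=3.0, rate=1200.0)
    m = add_white_noise(m, 1e-2, seed=3)
    m = common_average_reference(m)
    m = demean_channels(m)
    return source_space, lead, m


class TestScan:
    def test_one_output_per_node_with_bounded_kurtosis(self, scan_setup):
        space, lead, m = scan_setup
        outs = scan(space, lead, m, "unit_array_gain")
        assert len(outs) == space.node_count
        ok = [o for o in outs if o.ok]
        assert ok, "scan produced no usable nodes"
        assert all(o.kurtosis_output >= -2.0 for o in ok)
        assert all(o.variance_output >= 0.0 for o in ok)

    def test_distortionless_reconstruction_unit_gain(self, shells, eeg_sensors,
                                                     reference_sources):
        # noiseless single source with matched leadfield: W^T B recovers the
        # source waveform exactly up to the unit-gain constraint's scale
        gain = compute_leadfields(shells, eeg_sensors,
                                  reference_sources[:1]).node_gain(0)
        ori = np.array([0.0, 0.6, 0.8])
        wf = make_spike_waveform()
        m = assemble_measurement(gain @ ori, wf, [200], duration_s=1.0, rate=1200.0)
        cov = sample_covariance(m.data, loading=0.1)
        w = filter_weights(gain @ ori, cov, "unit_gain")
        src = np.zeros(m.n_samples)
        src[200:200 + len(wf)] = 100.0 * wf.samples  # amplitude in nAm
        recon = w @ m.data / 1e-3                    # undo µV-per-nAm unit scale
        assert np.allclose(recon, src, atol=1e-6 * np.max(np.abs(src)))
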