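"""Forward-model tests: shell cascade, spherical leadfields, source space."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from beamcascade import (ConfigurationError, ConstructionError, DegenerateInputError,
                         DomainError, build_source_space, compute_leadfields,
                         eeg_sphere_leadfield, forward, make_shell_model,
                         meg_sphere_leadfield, perturb_leadfield,
                         reference_orientations, OFFSET_BAND)
from oracles import geselowitz_sphere_field, homogeneous_sphere_potential

MODERATE_NODE = np.array([20.0, 10.0, 40.0])  # well-converged at 60 terms


class TestShellCascade:
    def test_3c_has_three_shells_with_printed_conductivities(self):
        m = make_shell_model("3C")
        assert len(m.radii) == 3
        assert m.conductivities == (0.33, 0.01, 0.43)

    def test_4c_contains_csf_shell(self):
        assert 1.79 in make_shell_model("4C").conductivities

    def test_cascade_is_deterministic(self):
        assert make_shell_model("4C") == make_shell_model("4C")

    def test_unknown_level_raises(self):
        with pytest.raises(ConfigurationError):
            make_shell_model("99C")

    def test_invalid_shells_rejected(self):
        with pytest.raises(ConfigurationError):
            forward.ShellModel((90.0, 80.0), (0.3, 0.3))
        with pytest.raises(ConfigurationError):
            forward.ShellModel((80.0,), (-0.3,))


class TestEEGLeadfield:
    def test_equal_conductivities_match_homogeneous_closed_form(self, eeg_sensors):
        eq = forward.ShellModel((80.0, 85.0, 90.0, 92.0), (0.33,) * 4, "eq")
        gain = eeg_sphere_leadfield(eq, eeg_sensors, MODERATE_NODE)
        for i, q in enumerate(np.eye(3)):
            ref = np.array([homogeneous_sphere_potential(92.0, 0.33, MODERATE_NODE, e, q)
                            for e in eeg_sensors.positions])
            ref -= ref.mean()
            assert np.max(np.abs(gain[:, i] - ref)) < 1e-6 * np.max(np.abs(ref))

    def test_common_average_reference_zero_column_sums(self, shells, eeg_sensors):
        gain = eeg_sphere_leadfield(shells, eeg_sensors, np.array([30.0, -20.0, 55.0]))
        assert np.max(np.abs(gain.sum(axis=0))) < 1e-12 * np.max(np.abs(gain))

    def test_linearity_of_moments(self, shells, eeg_sensors):
        gain = eeg_sphere_leadfield(shells, eeg_sensors, MODERATE_NODE)
        q = np.array([0.3, -1.2, 0.7])
        assert np.allclose(gain @ (2 * q), 2 * (gain @ q), rtol=1e-15)

    def test_node_outside_innermost_shell_rejected(self, shells, eeg_sensors):
        with pytest.raises(DomainError):
            eeg_sphere_leadfield(shells, eeg_sensors, np.array([0.0, 0.0, 81.0]))

    def test_truncation_warning_for_eccentric_node(self, shells, eeg_sensors):
        with pytest.warns(RuntimeWarning, match="not converged"):
            eeg_sphere_leadfield(shells, eeg_sensors, np.array([0.0, 0.0, 75.0]),
                                 n_terms=10)


class TestMEGLeadfield:
    def test_radial_dipole_is_silent(self, meg_sensors):
        node = np.array([30.0, 20.0, 55.0])
        gain = meg_sphere_leadfield(meg_sensors, node)
        radial = node / np.linalg.norm(node)
        assert np.linalg.norm(gain @ radial) < 1e-12 * np.linalg.norm(gain)

    def test_tangential_dipole_matches_quadrature_oracle(self):
        # magnetometer array so the oracle integrates a single field point
        pos = np.array([[0.0, 30.0, 108.0], [70.0, 10.0, 75.0], [-60.0, 40.0, 60.0]])
        mag = forward.SensorArray(positions=pos, modality="meg",
                                  orientations=pos / np.linalg.norm(pos, axis=1)[:, None])
        node = np.array([25.0, -10.0, 60.0])
        tang = np.cross(node, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        gain = meg_sphere_leadfield(mag, node)
        ours = gain @ tang
        for k in range(pos.shape[0]):
            b = geselowitz_sphere_field(pos[k], node, tang, R_mm=92.0, sigma=0.33)
            oracle = b @ mag.orientations[k]
            assert ours[k] == pytest.approx(oracle, rel=2e-3)

    def test_dipole_at_center_rejected(self, meg_sensors):
        with pytest.raises(DomainError):
            meg_sphere_leadfield(meg_sensors, np.zeros(3))


class TestReferenceOrientations:
    def test_unit_norm_and_orthogonal(self, rng):
        gain = rng.standard_normal((25, 3))
        qr, qt = reference_orientations(gain)
        assert np.linalg.norm(qr) == pytest.approx(1.0)
        assert np.linalg.norm(qt) == pytest.approx(1.0)
        assert abs(qr @ qt) < 1e-10

    def test_agree_with_svd_oracle(self, rng):
        gain = rng.standard_normal((25, 3))
        qr, qt = reference_orientations(gain)
        _, _, vt = np.linalg.svd(gain)
        assert abs(qr @ vt[-1]) == pytest.approx(1.0, abs=1e-10)
        assert abs(qt @ vt[0]) == pytest.approx(1.0, abs=1e-10)

    def test_spherical_meg_quasi_radial_is_radial(self, meg_sensors):
        node = np.array([35.0, -25.0, 50.0])
        qr, _ = reference_orientations(meg_sphere_leadfield(meg_sensors, node))
        assert abs(qr @ (node / np.linalg.norm(node))) > 1.0 - 1e-9

    def test_zero_gain_rejected(self):
        with pytest.raises(DegenerateInputError):
            reference_orientations(np.zeros((10, 3)))


class TestSourceSpace:
    def test_offset_band_holds_for_every_reference_source(
            self, shells, reference_sources, source_space):
        d, _ = cKDTree(source_space.node_positions).query(reference_sources)
        assert np.all(d > OFFSET_BAND[0]) and np.all(d < OFFSET_BAND[1])

    def test_node_count_and_containment(self, shells, source_space):
        assert source_space.node_count == 300
        assert np.all(np.linalg.norm(source_space.node_positions, axis=1)
                      < shells.inner_radius)

    def test_infeasible_offset_raises(self, shells):
        refs = np.array([[60.0, 0.0, 0.0], [60.05, 0.0, 0.0]])  # share nearest node
        with pytest.raises(ConstructionError):
            build_source_space(50, shells, refs, seed=0, cortex_radius=60.0)


class TestPerturbation:
    def test_level_zero_is_identity(self, shells, eeg_sensors, source_space):
        lead = compute_leadfields(shells, eeg_sensors, source_space.node_positions[:40])
        out = perturb_leadfield(lead, 0.0, seed=3)
        assert np.array_equal(out.gain, lead.gain)

    def test_relative_frobenius_norm_is_exact(self, shells, eeg_sensors, source_space):
        lead = compute_leadfields(shells, eeg_sensors, source_space.node_positions[:40])
        out = perturb_leadfield(lead, 0.1, seed=3)
        rel = np.linalg.norm(out.gain - lead.gain) / np.linalg.norm(lead.gain)
        assert rel == pytest.approx(0.1, abs=1e-3)

    def test_deterministic_and_reference_preserving(self, shells, eeg_sensors,
                                                    source_space):
        lead = compute_leadfields(shells, eeg_sensors, source_space.node_positions[:40])
        a = perturb_leadfield(lead, 0.05, seed=9)
        b = perturb_leadfield(lead, 0.05, seed=9)
        assert np.array_equal(a.gain, b.gain)
        assert np.max(np.abs(a.gain.sum(axis=0))) < 1e-12 * np.max(np.abs(a.gain))

    def test_negative_level_rejected(self, shells, eeg_sensors, source_space):
        lead = compute_leadfields(shells, eeg_sensors, source_space.node_positions[:5])
        with pytest.raises(ValueError):
            perturb_leadfield(lead, -0.1, seed=0)
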