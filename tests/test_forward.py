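"""Head-model physics oracles and EEG synthesis algebra."""

import numpy as np
import pytest

from assrmix.cochlea import NoiseSpec
from assrmix.forward import (
    Dipole,
    LeadField,
    Montage,
    ShellModel,
    default_dipoles,
    load_lead_field,
    save_lead_field,
    sphere_lead_field,
    sphere_potential,
    synthesize_eeg,
)
from assrmix.neuraldyn import SourceDynamics


from oracles import fibonacci_sphere, homogeneous_sphere_potential


@pytest.fixture(scope="module")
def montage():
    return Montage.standard_32()


class TestSpherePotential:
    def test_equal_conductivities_match_homogeneous_closed_form(self, montage):
        shells = ShellModel(conductivities=(0.33, 0.33, 0.33))
        elec = montage.positions(shells.scalp_radius)
        for dip in [
            Dipole(np.array([0.02, -0.01, 0.04]), np.array([0.3, -0.5, 0.8]), "d1"),
            Dipole(np.array([0.0, 0.0, 0.07]), np.array([0.0, 0.0, 1.0]), "d2"),
            Dipole(np.array([-0.05, 0.02, -0.01]), np.array([1.0, 0.0, 0.0]), "d3"),
        ]:
            v = sphere_potential(dip, elec, shells)
            ref = homogeneous_sphere_potential(dip, elec, shells.scalp_radius, 0.33)
            np.testing.assert_allclose(v, ref, rtol=1e-6)

    def test_mirror_symmetry(self):
        shells = ShellModel()
        # dipole in the sagittal plane, oriented within the plane:
        # left/right mirrored electrodes see identical potentials
        dip = Dipole(np.array([0.0, -0.02, 0.03]), np.array([0.0, 0.4, 0.9]), "mid")
        pts = np.array([
            [0.04, 0.03, 0.08], [-0.04, 0.03, 0.08],
            [0.07, -0.05, 0.03], [-0.07, -0.05, 0.03],
        ])
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * shells.scalp_radius
        v = sphere_potential(dip, pts, shells)
        assert v[0] == pytest.approx(v[1], rel=1e-10)
        assert v[2] == pytest.approx(v[3], rel=1e-10)

    def test_conductivity_scaling(self, montage):
        c = 3.7
        s1 = ShellModel()
        s2 = ShellModel(conductivities=tuple(c * x for x in s1.conductivities))
        dip = Dipole(np.array([0.03, 0.01, 0.02]), np.array([0.2, 0.9, 0.4]), "d")
        elec = montage.positions(s1.scalp_radius)
        np.testing.assert_allclose(
            sphere_potential(dip, elec, s2),
            sphere_potential(dip, elec, s1) / c, rtol=1e-10)

    def test_surface_mean_tends_to_zero_on_dense_grid(self):
        # surface-harmonic orthogonality: potentials average out over the scalp
        shells = ShellModel()
        grid = fibonacci_sphere(200) * shells.scalp_radius
        dip = Dipole(np.array([0.02, -0.03, 0.04]), np.array([0.5, 0.5, 0.7]), "d")
        v = sphere_potential(dip, grid, shells)
        assert abs(v.mean()) < 0.01 * np.abs(v).max()

    def test_dipole_outside_brain_shell_rejected(self, montage):
        shells = ShellModel()
        dip = Dipole(np.array([0.0, 0.0, 0.09]), np.array([0.0, 0.0, 1.0]), "out")
        with pytest.raises(ValueError, match="inside the brain shell"):
            sphere_potential(dip, montage.positions(shells.scalp_radius), shells)

    def test_central_dipole_finite(self, montage):
        shells = ShellModel()
        dip = Dipole(np.zeros(3), np.array([0.0, 0.0, 1.0]), "center")
        v = sphere_potential(dip, montage.positions(shells.scalp_radius), shells)
        assert np.all(np.isfinite(v)) and np.abs(v).max() > 0

    def test_skull_attenuation(self, montage):
        # realistic low-conductivity skull attenuates scalp potentials
        dip = Dipole(np.array([0.0, 0.0, 0.05]), np.array([0.0, 0.0, 1.0]), "d")
        elec = montage.positions(0.1)
        v_skull = sphere_potential(dip, elec, ShellModel())
        v_homog = sphere_potential(dip, elec, ShellModel(conductivities=(0.33, 0.33, 0.33)))
        assert np.abs(v_skull).max() < np.abs(v_homog).max()


class TestLeadFieldIO(object):
    def test_round_trip_identity(self, tmp_path, montage):
        lf = sphere_lead_field(default_dipoles()["neural"], montage)
        p = tmp_path / "lf.txt"
        save_lead_field(lf, p)
        back = load_lead_field(p, expected_electrodes=lf.electrode_labels,
                               expected_roles=lf.dipole_roles)
        np.testing.assert_allclose(back.matrix, lf.matrix, rtol=1e-12)
        assert back.provenance == "imported"

    def test_mismatched_labels_rejected(self, tmp_path, montage):
        lf = sphere_lead_field(default_dipoles()["artifact"], montage)
        p = tmp_path / "lf.txt"
        save_lead_field(lf, p)
        with pytest.raises(ValueError, match="labels"):
            load_lead_field(p, expected_electrodes=["Cz", "Pz"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            LeadField(np.zeros((3, 2)), ("a", "b"), ("x", "y"))


class TestSynthesis:
    @pytest.fixture()
    def small_sources(self, rng):
        n = 4000
        return SourceDynamics(
            sampling_rate_hz=1000.0,
            neural=rng.standard_normal((5, n)),
            artifact=rng.standard_normal(n),
        )

    @pytest.fixture()
    def lead_fields(self, montage):
        d = default_dipoles()
        return (sphere_lead_field(d["neural"], montage),
                sphere_lead_field(d["artifact"], montage))

    def test_mixture_identity_bit_exact(self, small_sources, lead_fields):
        lf1, lf2 = lead_fields
        mix, assr, art = synthesize_eeg(small_sources, lf1, lf2,
                                        sensor_noise=NoiseSpec(std=0.5), seed=9)
        # regenerate the sensor-noise realization from the same seed: the
        # mixture is exactly the sum of its three parts
        b = 0.5 * np.random.default_rng(9).standard_normal(assr.data.shape)
        np.testing.assert_array_equal(assr.data + art.data + b, mix.data)
        resid = mix.data - assr.data - art.data
        np.testing.assert_allclose(resid, b, atol=1e-10)
        assert b.std() == pytest.approx(0.5, rel=0.05)

    def test_zero_artifact_source(self, small_sources, lead_fields, montage):
        lf1, lf2 = lead_fields
        src = SourceDynamics(
            sampling_rate_hz=1000.0, neural=small_sources.neural,
            artifact=np.zeros(small_sources.n_samples))
        mix, assr, art = synthesize_eeg(src, lf1, lf2,
                                        sensor_noise=NoiseSpec(std=0.0), seed=0)
        assert np.all(art.data == 0.0)
        np.testing.assert_array_equal(mix.data, assr.data)

    def test_same_seed_reproducible(self, small_sources, lead_fields):
        lf1, lf2 = lead_fields
        a = synthesize_eeg(small_sources, lf1, lf2, seed=5)[0]
        b = synthesize_eeg(small_sources, lf1, lf2, seed=5)[0]
        np.testing.assert_array_equal(a.data, b.data)

    def test_dimension_mismatch_rejected(self, small_sources, lead_fields):
        lf1, lf2 = lead_fields
        with pytest.raises(ValueError):
            synthesize_eeg(small_sources, lf2, lf2)  # wrong dipole count

    def test_noiseless_mixture_rank_at_most_six(self, small_sources, lead_fields):
        lf1, lf2 = lead_fields
        mix, _, _ = synthesize_eeg(small_sources, lf1, lf2,
                                   sensor_noise=NoiseSpec(std=0.0), seed=0)
        ev = np.linalg.eigvalsh(np.cov(mix.data))
        assert (ev > 1e-10 * ev.max()).sum() <= 6


class TestScenarioTopographies:
    def test_artifact_maximal_ipsilateral(self, default_sim):
        # right-side implant: the mean |artifact| peaks at a right-hemisphere
        # electrode near the implantation site
        mean_abs = np.abs(default_sim.art.data).mean(axis=1)
        peak = default_sim.art.channel_labels[int(np.argmax(mean_abs))]
        montage = default_sim.montage
        x_coord = montage.directions[montage.index(peak), 0]
        assert x_coord > 0, f"artifact peak at {peak} is not ipsilateral"

    def test_artifact_dominates_neural_amplitudes(self, default_sim):
        from assrmix.icabench import _channel_amplitudes

        a_art = _channel_amplitudes(default_sim.art, default_sim.f_m, 20)
        a_assr = _channel_amplitudes(default_sim.assr, default_sim.f_m, 20)
        assert a_art.max() > 3 * a_assr.max()


class TestValidation:
    def test_shell_ordering_enforced(self):
        with pytest.raises(ValueError):
            ShellModel(radii=(0.1, 0.09, 0.092))
        with pytest.raises(ValueError):
            ShellModel(conductivities=(0.33, -0.01, 0.33))

    def test_montage_unique_labels(self):
        with pytest.raises(ValueError):
            Montage(("Cz", "Cz"), np.array([[0, 0, 1.0], [0, 1.0, 0]]))

    def test_default_montage_has_32_unit_directions(self, montage):
        assert montage.n_channels == 32
        np.testing.assert_allclose(np.linalg.norm(montage.directions, axis=1), 1.0)
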