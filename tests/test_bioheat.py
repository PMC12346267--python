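import numpy as np
import pytest

from pactherm import bioheat as bh


def uniform_optics(mu_a, mu_s=0.0, g=0.0):
    return {k: bh.OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g)
            for k in ("air", "water", "skin", "muscle", "tumor")}


class TestTissueModel:
    def test_tumor_volume_matches_ellipsoid(self):
        model = bh.build_tissue_model("water", voxel_size=0.25)
        vol = (model.labels == bh.TUMOR).sum() * model.voxel_size ** 3
        assert vol == pytest.approx(4 / 3 * np.pi * 3.5 * 4 * 2.5, rel=0.05)

    def test_tumor_absorption_boosted(self):
        model = bh.build_tissue_model("air", voxel_size=0.5)
        assert model.optics[bh.TUMOR].mu_a == pytest.approx(1.46)
        assert model.optics[bh.MUSCLE].mu_a == pytest.approx(0.1)

    def test_water_coupling_has_water_absorption(self):
        model = bh.build_tissue_model("water", voxel_size=0.5)
        assert model.optics[bh.COUPLING].mu_a == pytest.approx(0.02)
        air = bh.build_tissue_model("air", voxel_size=0.5)
        assert air.optics[bh.COUPLING].mu_a == 0.0

    def test_layer_thicknesses(self):
        model = bh.build_tissue_model("water", voxel_size=0.25)
        nz = model.shape[0]
        z = (np.arange(nz) + 0.5) * model.voxel_size
        col = model.labels[:, 2, 2]  # far from the tumor
        skin = z[col == bh.SKIN]
        muscle = z[col == bh.MUSCLE]
        assert skin.max() - skin.min() == pytest.approx(0.75 - 0.25, abs=1e-9)
        assert muscle.max() - muscle.min() == pytest.approx(11.0 - 0.25, abs=1e-9)

    def test_bad_voxel_size_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            bh.build_tissue_model("water", voxel_size=0.3)

    def test_bad_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            bh.build_tissue_model("oil")


class TestMonteCarlo:
    def test_beer_lambert_depth_profile(self):
        # pure absorber, no scattering: deposition ~ mu_a exp(-mu_a z)
        mu_a = 5.0  # 1/cm
        model = bh.build_tissue_model("water", voxel_size=0.5,
                                      optics=uniform_optics(mu_a))
        beam = bh.BeamSpec(gaussian_radius=16.0, iris_radius=2.0)
        pm = bh.mc_absorbed_power(model, beam, 10 ** 6, seed=1)
        prof = pm.values.sum(axis=(1, 2))
        prof = prof / prof.sum()
        dz = model.voxel_size / 10.0  # cm
        expect = np.exp(-mu_a * np.arange(model.shape[0]) * dz) \
            * (1 - np.exp(-mu_a * dz))
        expect = expect / expect.sum()
        # compare down to ~3 optical depths, where 1e6 photons give
        # sub-percent counting error per voxel
        sl = slice(0, 12)
        rel = np.abs(prof[sl] - expect[sl]) / expect[sl]
        assert rel.max() < 0.02

    def test_transparent_medium_all_escapes(self):
        model = bh.build_tissue_model("water", voxel_size=0.5,
                                      optics=uniform_optics(0.0))
        pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 5000, seed=2)
        assert pm.escaped_fraction == pytest.approx(1.0)
        assert not pm.values.any()

    def test_energy_conservation_exact(self):
        model = bh.build_tissue_model("water", voxel_size=0.5)
        pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 20000, seed=3)
        assert pm.conservation_error < 1e-6

    def test_seeded_reproducibility(self):
        model = bh.build_tissue_model("air", voxel_size=1.0)
        a = bh.mc_absorbed_power(model, bh.BeamSpec(), 5000, seed=4)
        b = bh.mc_absorbed_power(model, bh.BeamSpec(), 5000, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_layer_totals_stable_across_seeds(self):
        model = bh.build_tissue_model("water", voxel_size=1.0)
        totals = []
        for seed in range(10):
            pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 20000, seed=seed)
            totals.append([pm.values[model.labels == lab].sum()
                           for lab in (bh.SKIN, bh.MUSCLE, bh.TUMOR)])
        totals = np.array(totals)
        mean, sd = totals.mean(0), totals.std(0, ddof=1)
        assert np.all(np.abs(totals - mean) <= 3.5 * sd + 1e-12)

    def test_beam_wider_than_domain_rejected(self):
        model = bh.build_tissue_model("water", voxel_size=1.0)
        with pytest.raises(ValueError, match="iris"):
            bh.mc_absorbed_power(model, bh.BeamSpec(gaussian_radius=40.0,
                                                    iris_radius=15.0), 100)


class TestPennes:
    def zero_power(self, model):
        return bh.PowerMap(values=np.zeros(model.shape),
                           voxel_size=model.voxel_size, total_power=0.0,
                           escaped_fraction=1.0, deposited_fraction=0.0)

    def test_zero_source_uniform_boundaries_steady(self):
        model = bh.build_tissue_model("water", voxel_size=1.0)
        model.labels[:] = bh.MUSCLE  # all-tissue: every boundary at 37 C
        res = bh.pennes_simulate(model, self.zero_power(model), duration=0.5)
        assert np.abs(res.final_field - 37.0).max() < 1e-9

    def test_positive_source_monotone_heating(self):
        model = bh.build_tissue_model("water", voxel_size=1.0)
        pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 20000, seed=5)
        res = bh.pennes_simulate(model, pm, duration=1.0, dt=1.0)
        trace = res.probe_traces["tumor_center"]
        assert np.all(np.diff(trace) > -1e-6)

    def test_adi_matches_unsplit_backward_euler(self):
        model = bh.build_tissue_model("air", voxel_size=1.0)
        pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 20000, seed=6)
        adi = bh.pennes_simulate(model, pm, duration=0.5, dt=0.5, method="adi")
        ref = bh.pennes_simulate(model, pm, duration=0.5, dt=0.5, method="cg")
        tissue = model.labels != bh.COUPLING
        diff = np.abs(adi.final_field - ref.final_field)[tissue]
        rise = (ref.final_field - 37.0)[tissue].max()
        assert diff.max() < 0.02 * rise

    def test_uniform_source_cube_matches_analytic_steady_state(self):
        # all-tissue cube, Dirichlet walls, constant volumetric source:
        # steady solution is the classic triple-sine series for -k lap u = Q
        model = bh.build_tissue_model("water", voxel_size=0.5)
        model.labels[:] = bh.MUSCLE
        th = bh.ThermalProperties(1000.0, 1000.0, 0.5, 0.0)
        for lab in model.thermal:
            model.thermal[lab] = th
        q = 0.05  # W/cm^3
        pm = bh.PowerMap(values=np.full(model.shape, q), voxel_size=0.5,
                         total_power=1.0, escaped_fraction=0.0,
                         deposited_fraction=1.0)
        res = bh.pennes_simulate(model, pm, duration=60.0, dt=2.0)
        L, k, Q = 0.02, 0.5, q * 1e6
        modes = np.arange(1, 40, 2)
        i, j, l = np.meshgrid(modes, modes, modes, indexing="ij")
        lam = (np.pi / L) ** 2 * (i * i + j * j + l * l)
        coef = (4 / np.pi) ** 3 / (i * j * l) * (-1.0) ** ((i - 1) // 2) \
            * (-1.0) ** ((j - 1) // 2) * (-1.0) ** ((l - 1) // 2)
        u_center = Q * np.sum(coef / (k * lam))
        n = model.shape[0]
        center = res.final_field[n // 2 - 1:n // 2 + 1,
                                 n // 2 - 1:n // 2 + 1,
                                 n // 2 - 1:n // 2 + 1].mean()
        assert center - 37.0 == pytest.approx(u_center, rel=0.01)

    def test_perfusion_caps_temperature(self):
        # stronger perfusion pulls the plateau toward arterial temperature
        model = bh.build_tissue_model("water", voxel_size=1.0)
        pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 20000, seed=7)
        low = bh.pennes_simulate(model, pm, duration=2.0, dt=1.0)
        hot = {lab: bh.ThermalProperties(t.density, t.heat_capacity,
                                         t.conductivity, t.perfusion * 20)
               for lab, t in model.thermal.items()}
        model2 = bh.build_tissue_model("water", voxel_size=1.0, thermal=None)
        model2.thermal = hot
        high = bh.pennes_simulate(model2, pm, duration=2.0, dt=1.0)
        assert high.probe_final()["tumor_center"] < low.probe_final()["tumor_center"]

    def test_grid_mismatch_rejected(self):
        m1 = bh.build_tissue_model("water", voxel_size=1.0)
        m2 = bh.build_tissue_model("air", voxel_size=0.5)
        pm = self.zero_power(m2)
        with pytest.raises(ValueError, match="grid"):
            bh.pennes_simulate(m1, pm)

    def test_grid_convergence_of_tumor_center(self):
        # halving the voxel size changes the final tumor-centre temperature
        # by a few percent at most
        finals = {}
        for h in (1.0, 0.5):
            model = bh.build_tissue_model("water", voxel_size=h)
            pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 200000, seed=8)
            res = bh.pennes_simulate(model, pm, duration=2.0, dt=1.0)
            finals[h] = res.probe_final()["tumor_center"]
        rel = abs(finals[0.5] - finals[1.0]) / (finals[1.0] - 37.0)
        assert rel < 0.05


class TestCompare:
    def test_identical_inputs_identical_summaries(self):
        model = bh.build_tissue_model("water", voxel_size=1.0)
        pm = bh.mc_absorbed_power(model, bh.BeamSpec(), 20000, seed=9)
        res = bh.pennes_simulate(model, pm, duration=0.5, dt=0.5)
        cmp = bh.compare_configurations(res, res)
        assert cmp["air"]["probe_final"] == cmp["water"]["probe_final"]
        assert not cmp["submerged_max_is_deeper"]

    def test_grid_mismatch_rejected(self):
        m1 = bh.build_tissue_model("water", voxel_size=1.0)
        m2 = bh.build_tissue_model("air", voxel_size=0.5)
        pm1 = bh.mc_absorbed_power(m1, bh.BeamSpec(), 1000, seed=0)
        pm2 = bh.mc_absorbed_power(m2, bh.BeamSpec(), 1000, seed=0)
        r1 = bh.pennes_simulate(m1, pm1, duration=0.1, dt=1.0)
        r2 = bh.pennes_simulate(m2, pm2, duration=0.1, dt=1.0)
        with pytest.raises(ValueError, match="grids"):
            bh.compare_configurations(r1, r2)
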