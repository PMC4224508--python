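"""Diffusion operator, tensors, stimuli and time stepping."""

import numpy as np
import pytest

from nodalsim import (Simulation, StabilityError, build_tensor,
                      build_tensor_field, diffusion_term, make_anisotropic_slab,
                      make_strand, stable_dt)
from nodalsim.measurements import activation_times, conduction_velocity


class TestBuildTensor:
    def test_axis_aligned(self):
        D = build_tensor((1, 0, 0), 2.0, 0.2)
        assert np.allclose(D, np.diag([2.0, 0.2, 0.2]))

    def test_isotropic_limit(self):
        f = np.array([1.0, 2.0, 2.0]) / 3.0
        assert np.allclose(build_tensor(f, 7.0, 7.0), 7.0 * np.eye(3))

    def test_eigenstructure_random_fiber(self, rng):
        """Eigendecomposition oracle: eigenvalues {D_l, D_t, D_t} with the
        fibre as the leading eigenvector."""
        for _ in range(20):
            f = rng.normal(size=3)
            f /= np.linalg.norm(f)
            D = build_tensor(f, 3.0, 0.3)
            w, V = np.linalg.eigh(D)
            assert np.allclose(sorted(w), [0.3, 0.3, 3.0])
            lead = V[:, np.argmax(w)]
            assert abs(abs(np.dot(lead, f)) - 1.0) < 1e-10

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(ValueError):
            build_tensor((1, 1, 0), 2.0, 0.2)


@pytest.fixture(scope="module")
def slab_field(cfg):
    geom = make_anisotropic_slab(dims=(24, 16, 10))
    comps = build_tensor_field(geom, cfg)
    form = (geom.labels != 0).astype(np.int8)
    return geom, comps, form


class TestDiffusionOperator:
    def test_constant_field_zero(self, slab_field):
        _, comps, form = slab_field
        out = diffusion_term(np.full(form.shape, 0.7), comps, form)
        assert np.max(np.abs(out)) < 1e-12

    def test_shape_mismatch(self, slab_field):
        _, comps, form = slab_field
        with pytest.raises(ValueError):
            diffusion_term(np.zeros((3, 3, 3)), comps, form)

    def test_conservation_no_reaction(self, cfg, rng):
        """No-flux closed domain: total u conserved to <1e-8 relative
        over 1000 explicit steps (reaction off)."""
        geom = make_anisotropic_slab(dims=(16, 12, 8),
                                     fiber_axis=(1, 1, 0))
        comps = build_tensor_field(geom, cfg)
        form = (geom.labels != 0).astype(np.int8)
        u = rng.random(form.shape)
        total0 = u.sum()
        dt = stable_dt(comps, cfg)
        for _ in range(1000):
            u = u + dt * diffusion_term(u, comps, form)
        assert abs(u.sum() - total0) / abs(total0) < 1e-8
        # and the field homogenized toward the mean
        assert u.std() < 0.1 * rng.random(form.shape).std()

    def test_heat_kernel_variance_growth(self, cfg):
        """1-D Gaussian spreading under isotropic D matches the analytic
        solution: variance grows as 2 D t (within 1%)."""
        n = 201
        geom = make_strand(n_long=n, n_cross=1, tissue="atrial")
        comps = build_tensor_field(geom, cfg)
        form = (geom.labels != 0).astype(np.int8)
        dx = geom.dx_um / 1000.0
        x = (np.arange(n) - n // 2) * dx
        sig0 = 0.30  # mm
        u = np.exp(-x ** 2 / (2 * sig0 ** 2))[:, None, None]
        D_phys = cfg.diffusion_unit * cfg.tissues["atrial"].D  # mm^2/ms
        dt = stable_dt(comps, cfg)
        T = 2.0  # ms
        steps = int(round(T / dt))
        for _ in range(steps):
            u = u + dt * diffusion_term(u, comps, form)
        w = u[:, 0, 0]
        var = np.sum(w * x ** 2) / np.sum(w)
        expect = sig0 ** 2 + 2 * D_phys * (steps * dt)
        assert var == pytest.approx(expect, rel=0.01)


class TestStepping:
    def test_rest_state_stays_at_rest(self, cfg):
        sim = Simulation(make_strand(n_long=10, n_cross=3), cfg)
        sim.step(200)
        assert np.max(np.abs(sim.state.u)) < 1e-12
        assert np.max(np.abs(sim.state.v)) < 1e-12

    def test_instability_detected_and_named(self, cfg):
        sim = Simulation(make_strand(n_long=10, n_cross=3), cfg, dt=0.1)
        sim.apply_stimulus(sim.strand_stim_region())
        with pytest.raises(StabilityError, match="dt=0.1"):
            sim.step(500)

    def test_zero_duration_stimulus_is_a_no_op(self, cfg):
        sim = Simulation(make_strand(n_long=10, n_cross=3), cfg)
        sim.apply_stimulus(sim.strand_stim_region(), duration=0.0)
        sim.step(100)
        assert np.max(np.abs(sim.state.u)) < 1e-12

    def test_empty_stimulus_region_rejected(self, cfg):
        sim = Simulation(make_strand(n_long=10, n_cross=3), cfg)
        with pytest.raises(ValueError):
            sim.apply_stimulus(np.zeros(sim.geom.shape, dtype=bool))

    def test_set_u_stimulus_idempotent(self, cfg):
        """Applying the same set-u stimulus twice equals applying it once."""
        res = []
        for n_events in (1, 2):
            sim = Simulation(make_strand(), cfg)
            for _ in range(n_events):
                sim.add_stimulus(0.0, sim.strand_stim_region(), "set-u",
                                 1.0, 1.0)
            r = sim.run(30.0, probes={"mid": sim.geom.probes["mid"]})
            res.append(r.traces["mid"].u)
        assert np.array_equal(res[0], res[1])

    def test_strand_stimulus_propagates_to_far_end(self, cfg):
        sim = Simulation(make_strand(), cfg)
        sim.apply_stimulus(sim.strand_stim_region())
        r = sim.run(40.0, probes={"far": sim.geom.probes["far"]})
        assert len(activation_times(r.traces["far"])) == 1


@pytest.fixture(scope="module")
def strand_cv(cfg):
    def measure(dt=None, diffusion_scale=1.0, duration=40.0):
        sim = Simulation(make_strand(), cfg, dt=dt,
                         diffusion_scale=diffusion_scale)
        sim.apply_stimulus(sim.strand_stim_region())
        r = sim.run(duration, probes={})
        return conduction_velocity(r.activation, 10, 40)

    return measure


class TestConvergenceAndScaling:
    def test_cv_insensitive_to_dt_halving(self, cfg, strand_cv):
        sim = Simulation(make_strand(), cfg)
        cv1 = strand_cv(dt=sim.dt)
        cv2 = strand_cv(dt=sim.dt / 2)
        assert abs(cv2 - cv1) / cv1 < 0.01

    def test_cv_scales_as_sqrt_of_diffusion(self, strand_cv):
        """Doubling every diffusion coefficient raises conduction velocity
        by sqrt(2) within 3%."""
        cv1 = strand_cv()
        cv2 = strand_cv(diffusion_scale=2.0)
        assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.03)


class TestIsotropyAndAnisotropy:
    def test_cv_equal_along_all_axes_isotropic(self, cfg):
        """Planar-wave CV agrees within 2% along x, y and z in an
        isotropic slab."""
        cvs = []
        for axis in range(3):
            dims = [14, 14, 14]
            dims[axis] = 40
            geom = make_anisotropic_slab(dims=tuple(dims), tissue="atrial",
                                         fiber_axis=(1, 0, 0))
            geom.fibers = None  # isotropic tissue carries no fibres
            sim = Simulation(geom, cfg)
            mask = np.zeros(geom.shape, dtype=bool)
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 3)
            mask[tuple(sl)] = True
            sim.apply_stimulus(mask)
            r = sim.run(12.0, probes={})
            cvs.append(conduction_velocity(r.activation, 10, 30, axis=axis))
        assert max(cvs) / min(cvs) < 1.02

    def test_45_degree_fiber_cv_ratio_matches_axis_aligned(self, cfg):
        """Paired point-source simulations: the longitudinal/transverse
        activation-speed ratio with fibres at 45 degrees (measured along
        the diagonals) matches the axis-aligned ratio (measured along the
        axes) within 10% -- a discretization check on the mixed-derivative
        stencil, with wavefront-curvature effects common to both."""
        def ratio(fiber, d_long, d_trans):
            geom = make_anisotropic_slab(dims=(64, 64, 4),
                                         fiber_axis=fiber)
            sim = Simulation(geom, cfg)
            mask = np.zeros(geom.shape, dtype=bool)
            mask[30:34, 30:34, :] = True
            sim.apply_stimulus(mask)
            r = sim.run(40.0, probes={})
            t = np.nanmean(r.activation.times, axis=2)
            c = 32

            def speed(d):
                n = np.hypot(*d)
                t0 = t[c + 8 * d[0], c + 8 * d[1]]
                t1 = t[c + 20 * d[0], c + 20 * d[1]]
                return 12 * n * geom.dx_um / 1000.0 / (t1 - t0)

            return speed(d_long) / speed(d_trans)

        r_axis = ratio((1, 0, 0), (1, 0), (0, 1))
        r_diag = ratio((1, 1, 0), (1, 1), (1, -1))
        assert r_diag == pytest.approx(r_axis, rel=0.10)


class TestSANTissue:
    def test_san_cube_fires_at_cell_period(self, cfg):
        """A free-running SAN cube activates globally at the isolated-cell
        period within 2%."""
        from nodalsim import san_limit_cycle
        from nodalsim.geometry import Geometry, LabelVolume
        from nodalsim.geometry import FiberField

        labels = np.full((8, 8, 8), 3, dtype=np.int8)
        lx = np.zeros(labels.shape, np.float32)
        ly = np.ones(labels.shape, np.float32)
        lz = np.zeros(labels.shape, np.float32)
        geom = Geometry(LabelVolume(labels), FiberField(lx, ly, lz))
        sim = Simulation(geom, cfg)
        r = sim.run(1200.0, probes={"c": (4, 4, 4)})
        acts = activation_times(r.traces["c"])
        assert len(acts) >= 3
        period = float(np.mean(np.diff(acts)))
        cell_cl = san_limit_cycle(cfg.tissues["san"], cfg)[3]
        assert period == pytest.approx(cell_cl, rel=0.02)


class TestPassiveBlock:
    def test_wave_blocked_by_passive_slab(self, cfg):
        """A 10-element passive slab in an atrial strand stops the wave:
        no activation beyond the slab."""
        geom = make_strand(n_long=60)
        geom.volume.labels[30:40] = 7
        sim = Simulation(geom, cfg)
        sim.apply_stimulus(sim.strand_stim_region())
        r = sim.run(120.0, probes={"beyond": (50, 2, 2),
                                   "before": (20, 2, 2)})
        assert len(activation_times(r.traces["before"])) == 1
        assert len(activation_times(r.traces["beyond"])) == 0


class TestExports:
    def test_vtk_and_frame_snapshots(self, cfg, tmp_path, rng):
        from nodalsim.solver import export_vtk, save_frames
        import json

        geom = make_strand(n_long=8, n_cross=3)
        field = rng.random(geom.shape)
        vtk = tmp_path / "u.vtk"
        export_vtk(vtk, field, geom.dx_um)
        text = vtk.read_text().splitlines()
        assert text[3] == "DATASET STRUCTURED_POINTS"
        assert f"DIMENSIONS {geom.shape[0]} {geom.shape[1]} " \
               f"{geom.shape[2]}" in text
        n_vals = sum(len(line.split()) for line in text[10:])
        assert n_vals == field.size

        save_frames(str(tmp_path / "run"), [field, field * 0.5],
                    [0.0, 1.0], geom, dt=0.005)
        with np.load(tmp_path / "run.npz") as z:
            assert np.allclose(z["frame_0001"], field * 0.5)
        meta = json.loads((tmp_path / "run.json").read_text())
        assert meta["frame_times_ms"] == [0.0, 1.0]
        assert meta["dims"] == list(geom.shape)
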