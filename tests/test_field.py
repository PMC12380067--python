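"""Field solver gates: analytic oracle, conservation, linearity, meshes."""

import numpy as np
import pytest

from flexb2b.field import (
    DEFAULT_GRIDS,
    ActivationModel,
    MatchingOutOfRange,
    TissueModel,
    activated_count,
    activated_volume,
    build_geometry,
    matching_current,
    solve_field,
    sweep_current,
)


class TestGeometry:
    def test_flexible_array(self, tissue):
        g = build_geometry("flexible_array", tissue)
        assert len(g.rects) == 8
        assert g.glial_thickness == 0.0
        # 16 um x 12 um sites
        x0, x1, y0, y1 = g.rects[0]
        assert (x1 - x0) == pytest.approx(12e-6)
        assert (y1 - y0) == pytest.approx(16e-6)
        # 30 um center-to-center pitch
        c0 = 0.5 * (g.rects[0][2] + g.rects[0][3])
        c1 = 0.5 * (g.rects[1][2] + g.rects[1][3])
        assert c1 - c0 == pytest.approx(30e-6)

    def test_rigid_array_same_sites_with_glia(self, tissue):
        f = build_geometry("flexible_array", tissue)
        r = build_geometry("rigid_array", tissue)
        assert r.rects == f.rects
        assert r.glial_thickness == pytest.approx(40e-6)

    def test_microwire(self, tissue):
        m = build_geometry("microwire", tissue)
        assert m.disc_radius == pytest.approx(50e-6)
        assert m.glial_thickness == pytest.approx(40e-6)
        assert m.n_sites == 1

    def test_unknown_kind(self, tissue):
        with pytest.raises(ValueError):
            build_geometry("nanowire", tissue)


class TestSolver:
    def test_analytic_disc_on_axis(self, bare_wire_solution):
        """Bare microwire against the closed-form uniform-current disc."""
        sol = bare_wire_solution
        a, I = 50e-6, 10e-6
        j0 = I / (np.pi * a * a)
        ix = np.argmin(np.abs(sol.grid.xc))
        iy = np.argmin(np.abs(sol.grid.yc))
        for z_um in (20, 50, 100, 150):
            iz = np.argmin(np.abs(sol.grid.zc - z_um * 1e-6))
            z = sol.grid.zc[iz]
            analytic = j0 * (1 - z / np.sqrt(z * z + a * a))
            assert sol.j_magnitude[ix, iy, iz] \
                == pytest.approx(analytic, rel=0.10)

    def test_current_conservation(self, coarse_wire_solution,
                                  coarse_flex_solution):
        assert coarse_wire_solution.conservation_error < 0.02
        assert coarse_flex_solution.conservation_error < 0.02

    def test_linearity_in_current(self, tissue, coarse_wire_solution):
        geom = build_geometry("microwire", tissue)
        sol2 = solve_field(geom, tissue, 2.0, grid="coarse")
        np.testing.assert_allclose(sol2.potential,
                                   2 * coarse_wire_solution.potential,
                                   rtol=1e-6, atol=1e-12)

    def test_nonpositive_current_rejected(self, tissue):
        geom = build_geometry("microwire", tissue)
        with pytest.raises(ValueError):
            solve_field(geom, tissue, 0.0, grid="coarse")


class TestActivation:
    def test_below_threshold_counts_zero(self, coarse_wire_solution):
        # at 1 uA through the glial standoff nothing exceeds threshold
        assert activated_volume(coarse_wire_solution, 1000.0) == 0.0

    def test_density_linearity(self, coarse_flex_solution):
        m1 = ActivationModel(neuron_density=1e12)
        m2 = ActivationModel(neuron_density=2e12)
        c1 = activated_count(coarse_flex_solution, m1)
        c2 = activated_count(coarse_flex_solution, m2)
        assert c1 > 0
        assert c2 == pytest.approx(2 * c1)

    def test_handbuilt_uniform_field(self, coarse_flex_solution):
        """Forcing |J| uniform over a known sub-volume gives density x V."""
        import copy
        sol = copy.copy(coarse_flex_solution)
        sol.j_magnitude = np.zeros_like(sol.j_magnitude)
        sub = (slice(0, 5), slice(0, 5), slice(0, 5))
        sol.j_magnitude[sub] = 2000.0
        v_known = float(sol.grid.cell_volumes()[sub].sum())
        model = ActivationModel(neuron_density=1e9)
        assert activated_count(sol, model) \
            == pytest.approx(1e9 * v_known)


class TestSweepAndMatching:
    def test_counts_nondecreasing(self, tissue, coarse_wire_solution):
        geom = build_geometry("microwire", tissue)
        df = sweep_current(geom, tissue, currents_uA=np.arange(1, 101, 5),
                           solution=coarse_wire_solution)
        assert (np.diff(df["count"].values) >= 0).all()

    def test_rescale_equals_resolve(self, tissue, coarse_wire_solution):
        """Linearity shortcut: rescaled counts match independent solves."""
        geom = build_geometry("microwire", tissue)
        model = ActivationModel()
        for current in (40.0, 70.0):
            resolved = solve_field(geom, tissue, current, grid="coarse")
            direct = activated_count(resolved, model)
            rescaled = activated_count(coarse_wire_solution, model,
                                       scale=current)
            assert rescaled == pytest.approx(direct, rel=1e-6)

    def test_self_matching_returns_input_current(self, tissue,
                                                 coarse_flex_solution):
        model = ActivationModel()
        ref = activated_count(coarse_flex_solution, model)
        matched = matching_current(
            build_geometry("flexible_array", tissue), tissue, model, ref,
            solution=coarse_flex_solution)
        assert matched == pytest.approx(5.0, abs=0.1)

    def test_glia_never_lowers_matching_current(
            self, tissue, coarse_flex_solution, coarse_rigid_solution):
        model = ActivationModel()
        ref = activated_count(coarse_flex_solution, model)
        i_rigid = matching_current(
            build_geometry("rigid_array", tissue), tissue, model, ref,
            solution=coarse_rigid_solution)
        assert i_rigid >= 5.0

    def test_out_of_range_reported(self, tissue, coarse_wire_solution):
        model = ActivationModel()
        huge = activated_count(coarse_wire_solution, model,
                               scale=100.0) * 50
        with pytest.raises(MatchingOutOfRange):
            matching_current(build_geometry("microwire", tissue), tissue,
                             model, huge, solution=coarse_wire_solution)

    def test_vtk_export_header_and_size(self, coarse_wire_solution,
                                        tmp_path):
        from flexb2b.field import export_vtk
        path = tmp_path / "wire.vtk"
        export_vtk(coarse_wire_solution, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# vtk DataFile")
        nx, ny, nz = coarse_wire_solution.grid.shape
        assert f"DIMENSIONS {nx} {ny} {nz}" in lines
        assert sum(l.startswith("SCALARS") for l in lines) == 3

    def test_mesh_refinement_stability(self, tissue, coarse_flex_solution):
        """Activated volume changes by <10% from coarse to default grid."""
        geom = build_geometry("flexible_array", tissue)
        fine = solve_field(geom, tissue, 5.0,
                           grid=DEFAULT_GRIDS["flexible_array"])
        v_coarse = activated_volume(coarse_flex_solution)
        v_fine = activated_volume(fine)
        assert v_coarse == pytest.approx(v_fine, rel=0.10)
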