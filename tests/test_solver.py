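import numpy as np
import pytest

from fruitflux.geometry import CYT, WALL, LayoutSpec, build_layout
from fruitflux.scenarios import (
    FacetStrengthTable,
    TransportParameters,
    assemble_permeabilities,
    conceptual_table,
)
from fruitflux.solver import (
    SolverError,
    SolverSettings,
    compute_fluxes,
    integrate,
    mass_budget,
    steady_state,
)

from dense_reference import dense_steady_state

NO_CARRIERS = FacetStrengthTable("none")


def _solve(layout, table, params, **kw):
    perms = assemble_permeabilities(layout, table, params)
    return perms, steady_state(layout, perms, params, **kw)


class TestSteadyState:
    def test_closed_homogeneous_fixed_point(self, tiny_layout):
        """No sink, no source gradients: cytosol p/d, wall scaled by the
        background permeability ratio (zero membrane flux)."""
        params = TransportParameters(
            apical_source=0.0, basal_open=False, production=2e-3, decay=1e-3
        )
        _, conc = _solve(tiny_layout, NO_CARRIERS, params)
        cyt = conc.values[tiny_layout.class_map == CYT]
        wall = conc.values[tiny_layout.class_map == WALL]
        np.testing.assert_allclose(cyt, 2.0, rtol=1e-9)
        np.testing.assert_allclose(
            wall, (params.P_bg_eff / params.P_bg_in) * 2.0, rtol=1e-9
        )

    def test_zero_sources_zero_field(self, tiny_layout):
        params = TransportParameters(production=0.0, apical_source=0.0)
        _, conc = _solve(tiny_layout, NO_CARRIERS, params)
        np.testing.assert_allclose(conc.values, 0.0, atol=1e-14)

    @pytest.mark.parametrize("model", ["basic", "export", "import"])
    def test_matches_dense_reference(self, tiny_layout, model):
        """Direct sparse solve equals a brute-force dense solve of the same
        balance equations (independent assembly path)."""
        params = TransportParameters()
        table = conceptual_table(model)
        _, conc = _solve(tiny_layout, table, params)
        ref = dense_steady_state(tiny_layout, table, params)
        scale = np.abs(ref).max()
        assert np.abs(conc.values - ref).max() / scale < 1e-8

    def test_singular_without_sink(self, tiny_layout):
        params = TransportParameters(decay=0.0, basal_open=False)
        perms = assemble_permeabilities(tiny_layout, NO_CARRIERS, params)
        with pytest.raises(SolverError):
            steady_state(tiny_layout, perms, params)

    def test_linearity_in_sources(self, small_layout, params):
        perms = assemble_permeabilities(
            small_layout, conceptual_table("export"), params
        )
        a1 = steady_state(small_layout, perms, params)
        doubled = TransportParameters(
            production=2 * params.production, apical_source=2 * params.apical_source
        )
        a2 = steady_state(small_layout, perms, doubled)
        np.testing.assert_allclose(a2.values, 2 * a1.values, rtol=1e-9, atol=1e-14)

    def test_mirror_symmetric_steady_state(self, export_state, small_layout):
        conc, _ = export_state
        m = small_layout.mirror_column_map(0)
        scale = conc.values.max()
        assert np.abs(conc.values - conc.values[:, m]).max() / scale < 1e-10

    def test_periodic_shift_invariance(self, export_state, small_layout):
        conc, _ = export_state
        shifted = np.roll(conc.values, small_layout.ring_period, axis=1)
        assert np.abs(conc.values - shifted).max() / conc.values.max() < 1e-10

    def test_nonnegative_and_finite(self, basic_state):
        conc, _ = basic_state
        assert np.isfinite(conc.values).all()
        assert (conc.values >= -1e-12).all()


class TestExplicitMode:
    def test_integrate_fixed_point(self, tiny_layout):
        params = TransportParameters()
        perms = assemble_permeabilities(
            tiny_layout, conceptual_table("export"), params
        )
        direct = steady_state(tiny_layout, perms, params)
        later = integrate(tiny_layout, perms, params, direct, t_end=2.0)
        np.testing.assert_allclose(later.values, direct.values, rtol=1e-6, atol=1e-12)

    def test_explicit_converges_to_direct(self, tiny_layout):
        params = TransportParameters()
        perms = assemble_permeabilities(
            tiny_layout, conceptual_table("export"), params
        )
        direct = steady_state(tiny_layout, perms, params)
        explicit = steady_state(
            tiny_layout, perms, params,
            settings=SolverSettings(mode="explicit", tol=1e-10),
        )
        scale = direct.values.max()
        assert np.abs(explicit.values - direct.values).max() / scale < 1e-6

    def test_dt_stability_bound_enforced(self, tiny_layout, params):
        perms = assemble_permeabilities(tiny_layout, NO_CARRIERS, params)
        bad = SolverSettings(mode="explicit", dt=1.0)
        with pytest.raises(SolverError):
            steady_state(tiny_layout, perms, params, settings=bad)


class TestFluxes:
    def test_equilibrium_field_has_zero_fluxes(self, tiny_layout):
        params = TransportParameters(apical_source=0.0, basal_open=False)
        perms = assemble_permeabilities(tiny_layout, NO_CARRIERS, params)
        values = np.where(
            tiny_layout.class_map == CYT, 1.0, params.P_bg_eff / params.P_bg_in
        )
        from fruitflux.solver import ConcentrationField

        conc = ConcentrationField(tiny_layout, values)
        flux = compute_fluxes(conc, tiny_layout, perms, params)
        assert np.abs(flux.flux_h).max() < 1e-14
        assert np.abs(flux.flux_v).max() < 1e-14

    def test_ficks_law_across_wall_step(self, tiny_layout, params):
        """An imposed concentration step across a wall-wall interface yields
        D_wall * delta / h with the correct sign."""
        from fruitflux.solver import ConcentrationField

        perms = assemble_permeabilities(tiny_layout, NO_CARRIERS, params)
        adj = tiny_layout.adjacency()
        rr, cc = np.nonzero(adj.v_kind == 2)
        r, c = rr[0], cc[0]
        values = np.zeros_like(tiny_layout.class_map, dtype=float)
        values[r, c] = 3.0  # upper site high, lower site zero
        conc = ConcentrationField(tiny_layout, values)
        flux = compute_fluxes(conc, tiny_layout, perms, params)
        assert flux.flux_v[r, c] == pytest.approx(
            params.D_wall * 3.0 / tiny_layout.h
        )

    def test_divergence_balances_sources(self, export_state, small_layout, params):
        """At steady state, the per-site flux divergence equals the local net
        source everywhere away from the basal exit row."""
        conc, flux = export_state
        h = small_layout.h
        nr, nc = conc.values.shape
        inflow = np.zeros((nr, nc))
        inflow += np.roll(flux.flux_h, 1, axis=1)  # from the left
        inflow -= flux.flux_h  # to the right
        inflow[1:, :] += flux.flux_v  # from above
        inflow[:-1, :] -= flux.flux_v  # to below
        inflow /= h
        cyt = small_layout.class_map == CYT
        source = np.where(cyt, params.production, 0.0)
        band = small_layout.cell_row_sites(0)
        source[band][cyt[band]] += params.apical_source
        source -= np.where(cyt, params.decay * conc.values, 0.0)
        resid = inflow + source
        resid[small_layout.basal_row] = 0.0  # Dirichlet exit row
        assert np.abs(resid).max() / conc.values.max() < 1e-9


class TestMassBudget:
    def test_closed_homogeneous_budget(self, tiny_layout):
        params = TransportParameters(
            apical_source=0.0, basal_open=False, production=2e-3, decay=1e-3
        )
        perms = assemble_permeabilities(tiny_layout, NO_CARRIERS, params)
        conc = steady_state(tiny_layout, perms, params)
        flux = compute_fluxes(conc, tiny_layout, perms, params)
        b = mass_budget(conc, flux, tiny_layout, params)
        assert b["basal_efflux"] == 0.0
        assert b["production"] == pytest.approx(b["decay"], rel=1e-9)

    def test_export_steady_state_closes(self, export_state, small_layout, params):
        conc, flux = export_state
        b = mass_budget(conc, flux, small_layout, params)
        total_in = b["production"] + b["apical_input"]
        assert abs(b["net"]) / total_in < 1e-6

    def test_zero_field_budget(self, tiny_layout, params):
        from fruitflux.solver import ConcentrationField

        perms = assemble_permeabilities(tiny_layout, NO_CARRIERS, params)
        conc = ConcentrationField(tiny_layout, np.zeros_like(tiny_layout.class_map, dtype=float))
        flux = compute_fluxes(conc, tiny_layout, perms, params)
        b = mass_budget(conc, flux, tiny_layout, params)
        assert b["decay"] == 0.0
        assert b["basal_efflux"] == 0.0
        assert b["production"] > 0.0
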