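import numpy as np
import pytest

from fruitflux.geometry import CYT, LIGNIFYING, REPLUM, SEPARATION, VALVE, LayoutSpec, build_layout
from fruitflux.observables import (
    FLUX_BARRIER,
    FLUX_PASSAGE,
    IndeterminateRegimeError,
    ObservableError,
    SweepResult,
    classify_regime,
    minimum_metrics,
    sweep_strength,
    threshold_strength,
    vm_flux_metrics,
    vm_minimum_ratio,
)
from fruitflux.scenarios import TransportParameters, assemble_permeabilities, conceptual_table
from fruitflux.solver import ConcentrationField, compute_fluxes


def _uniform(layout, value=1.0):
    return ConcentrationField(layout, np.full(layout.class_map.shape, float(value)))


def _synthetic_sweep(ratio, flux):
    n = len(ratio)
    z = np.zeros(n)
    return SweepResult(
        scenario="synthetic", transporter="PIN3", cell_types=(SEPARATION,),
        strengths=np.logspace(0, 1, n), ratio=np.asarray(ratio, dtype=float),
        sep_mean=z, replum_mean=z, valve_mean=z,
        transversal=np.asarray(flux, dtype=float), transversal_abs=np.abs(flux),
        parallel=z,
    )


class TestMinimumRatio:
    def test_uniform_field_gives_one(self, small_layout):
        assert vm_minimum_ratio(_uniform(small_layout), small_layout) == pytest.approx(1.0)

    def test_basic_model_is_a_maximum(self, basic_state, small_layout):
        conc, _ = basic_state
        assert vm_minimum_ratio(conc, small_layout) > 1.0

    def test_export_model_is_a_minimum(self, export_state, small_layout):
        conc, _ = export_state
        assert vm_minimum_ratio(conc, small_layout) < 1.0

    def test_scale_invariance(self, export_state, small_layout):
        conc, _ = export_state
        scaled = ConcentrationField(small_layout, 7.5 * conc.values)
        assert vm_minimum_ratio(scaled, small_layout) == pytest.approx(
            vm_minimum_ratio(conc, small_layout)
        )

    def test_mirror_and_shift_invariance(self, export_state, small_layout):
        conc, _ = export_state
        r0 = vm_minimum_ratio(conc, small_layout)
        m = small_layout.mirror_column_map(0)
        mirrored = ConcentrationField(small_layout, conc.values[:, m])
        shifted = ConcentrationField(
            small_layout, np.roll(conc.values, small_layout.ring_period, axis=1)
        )
        assert vm_minimum_ratio(mirrored, small_layout) == pytest.approx(r0)
        assert vm_minimum_ratio(shifted, small_layout) == pytest.approx(r0)

    def test_no_vm_error(self):
        layout = build_layout(
            LayoutSpec(stage="15", rows=1, valve_files=1, replum_files=1,
                       valve_width=4.0, replum_width=4.0, vm_width=4.0,
                       cell_height=4.0)
        )
        with pytest.raises(ObservableError):
            vm_minimum_ratio(_uniform(layout, 0.0), layout)  # zero replum


class TestFluxMetrics:
    def test_zero_field(self, small_layout, params):
        perms = assemble_permeabilities(small_layout, conceptual_table("basic"), params)
        conc = _uniform(small_layout, 0.0)
        flux = compute_fluxes(conc, small_layout, perms, params)
        fm = vm_flux_metrics(flux, small_layout)
        assert fm.transversal == 0.0
        assert fm.parallel == 0.0

    def test_imposed_gradient_matches_ficks_sum(self, params):
        """A linear circumferential gradient over an undivided VM file gives a
        cut flux equal to the Fick sum over the crossed interfaces."""
        layout = build_layout(LayoutSpec(stage="15", rows=3, valve_files=2))
        slope = 0.01  # conc per um
        cols = np.arange(layout.ncols) * layout.h
        values = np.tile(cols * slope, (layout.nrows, 1))
        perms = assemble_permeabilities(layout, conceptual_table("basic"), params)
        flux = compute_fluxes(
            ConcentrationField(layout, values), layout, perms, params
        )
        strip = layout.vm_strips[0]
        f = layout.files[strip.file_indices[0]]
        cut_col = f.col0 + f.width // 2 - 1
        rows = layout.middle_third_rows()
        kinds = layout.adjacency().h_kind[rows, cut_col]
        n_cyt = int((kinds == 1).sum())
        n_wall = int((kinds == 2).sum())
        expected = -slope * layout.h * (n_cyt * params.D_cyt + n_wall * params.D_wall)
        line = flux.flux_h[rows, cut_col] * layout.h
        assert line.sum() == pytest.approx(expected)

    def test_symmetric_field_has_symmetric_strip_fluxes(self, export_state, small_layout):
        _, flux = export_state
        fm = vm_flux_metrics(flux, small_layout)
        per = np.asarray(fm.per_strip_transversal)
        np.testing.assert_allclose(per, per.mean(), rtol=1e-8)


@pytest.fixture(scope="module")
def export_sweep(meso_layout, params):
    return sweep_strength(
        conceptual_table("export"), "PIN3", (SEPARATION, LIGNIFYING),
        np.logspace(-1.3, 0, 5), meso_layout, params,
    )


@pytest.fixture(scope="module")
def import_sweep(meso_layout, params):
    return sweep_strength(
        conceptual_table("import"), "LAX1", (VALVE, REPLUM),
        np.logspace(0, 1.6, 5), meso_layout, params,
    )


class TestSweep:
    def test_export_sweep_deepens_minimum_and_raises_flux(self, export_sweep):
        """Stronger VM efflux: strictly deeper minimum, higher transversal
        throughput overall."""
        assert (np.diff(export_sweep.ratio) < 0).all()
        assert np.abs(export_sweep.transversal[-1]) > np.abs(export_sweep.transversal[0])

    def test_import_sweep_starves_vm_flux(self, import_sweep):
        """Stronger surrounding import deepens the minimum while the VM
        through-flux collapses."""
        assert (np.diff(import_sweep.ratio) < 0).all()
        assert np.abs(import_sweep.transversal[-1]) < 0.2 * np.abs(
            import_sweep.transversal[0]
        )

    def test_single_point_sweep_matches_plain_run(self, small_layout, params, export_state):
        sw = sweep_strength(
            conceptual_table("export"), "PIN3", (SEPARATION, LIGNIFYING),
            [1.0], small_layout, params,
        )
        conc, _ = export_state
        assert sw.ratio[0] == pytest.approx(vm_minimum_ratio(conc, small_layout))

    def test_invalid_grids_rejected(self, small_layout, params):
        with pytest.raises(ObservableError):
            sweep_strength(conceptual_table("export"), "PIN3", (SEPARATION,),
                           [], small_layout, params)
        with pytest.raises(ObservableError):
            sweep_strength(conceptual_table("export"), "PIN3", (SEPARATION,),
                           [1.0, 0.5], small_layout, params)

    def test_frame_round_trip(self, export_sweep, tmp_path):
        path = tmp_path / "sweep.csv"
        export_sweep.to_frame().to_csv(path, index=False)
        import pandas as pd

        again = pd.read_csv(path)
        np.testing.assert_allclose(again["ratio_sep_replum"], export_sweep.ratio)


class TestThreshold:
    def test_log_linear_interpolation(self):
        sw = _synthetic_sweep(ratio=[2.0, 0.5], flux=[1.0, 2.0])
        # crossing 1.0 two thirds of the way in log strength: 10**(2/3)
        assert threshold_strength(sw) == pytest.approx(10 ** (2 / 3))

    def test_never_met_returns_none(self):
        sw = _synthetic_sweep(ratio=[3.0, 2.0], flux=[1.0, 2.0])
        assert threshold_strength(sw) is None

    def test_already_below_at_first_point(self):
        sw = _synthetic_sweep(ratio=[0.8, 0.5], flux=[1.0, 2.0])
        assert threshold_strength(sw) == pytest.approx(1.0)


class TestRegime:
    def test_synthetic_passage_and_barrier(self):
        ratio = [2.0, 1.0, 0.5, 0.25]
        assert classify_regime(_synthetic_sweep(ratio, [1, 2, 3, 4])) == FLUX_PASSAGE
        assert classify_regime(_synthetic_sweep(ratio, [4, 3, 2, 1])) == FLUX_BARRIER

    def test_constant_flux_indeterminate(self):
        with pytest.raises(IndeterminateRegimeError):
            classify_regime(_synthetic_sweep([2.0, 1.0, 0.5, 0.25], [1, 1, 1, 1]))

    def test_export_sweep_is_flux_passage(self, export_sweep):
        assert classify_regime(export_sweep) == FLUX_PASSAGE

    def test_import_sweep_is_flux_barrier(self, import_sweep):
        assert classify_regime(import_sweep) == FLUX_BARRIER
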