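"""Summary statistics of the auxin field and transporter-strength sweeps.

The depth of the valve-margin (VM) auxin minimum is quantified as the
ratio between the mean cytosolic auxin concentration in the separation
layer and in the bordering replum cell file; a ratio below 1 means a
minimum has formed.  Transversal fluxes crossing the VM perpendicular to
its axis, together with this ratio, discriminate the two regimes that can
generate a minimum: a flux-passage process (efflux-driven; transversal
flux grows as the minimum deepens) and a flux-barrier process
(import-driven; the VM carries negligible and shrinking through-flux).

All tissue-level statistics are evaluated on the middle third of the cell
rows, away from the apical source and the basal sink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .geometry import (
    SEPARATION,
    VALVE,
    VM_UNDIVIDED,
    StripInfo,
    TissueLayout,
)
from .scenarios import (
    FacetStrengthTable,
    TransportParameters,
    assemble_permeabilities,
    scale_transporter,
)
from .solver import (
    ConcentrationField,
    FluxField,
    SolverSettings,
    compute_fluxes,
    steady_state,
)


class ObservableError(ValueError):
    pass


class IndeterminateRegimeError(RuntimeError):
    """Raised when a sweep shows no robust monotone flux/ratio relation."""


@dataclass(frozen=True)
class MinimumMetrics:
    """Depth and absolute levels of the VM auxin minimum."""

    ratio_sep_replum: float
    sep_mean: float
    replum_mean: float
    valve_mean: float
    per_strip_ratio: tuple[float, ...] = ()


@dataclass(frozen=True)
class FluxMetrics:
    """Net VM fluxes in conc um^2/s, averaged over the four VM strips.

    ``transversal`` is the net horizontal flux through a vertical cut at
    each VM strip midline, summed over the evaluation row window and
    oriented from valve towards replum.  ``transversal_abs`` sums
    magnitudes instead of the net.  ``parallel`` is the net basipetal flux
    within the VM files through a horizontal cut at mid-window.
    """

    transversal: float
    transversal_abs: float
    parallel: float
    per_strip_transversal: tuple[float, ...] = ()


# ----------------------------------------------------------------------
# helpers on the layout


def _sep_file_of_strip(layout: TissueLayout, strip: StripInfo):
    """The separation-layer (or undivided VM) file of one VM strip."""
    for fi in strip.file_indices:
        if layout.files[fi].cell_type in (SEPARATION, VM_UNDIVIDED):
            return layout.files[fi]
    raise ObservableError("VM strip without separation-layer file")


def _bordering_replum_file(layout: TissueLayout, strip: StripInfo):
    """The replum file directly adjacent to the strip's separation layer."""
    rep_strips = [s for s in layout.strips if s.tissue == "replum"]
    rep = rep_strips[strip.replum_strip]
    fid = rep.file_indices[0] if strip.toward_replum > 0 else rep.file_indices[-1]
    return layout.files[fid]


def _file_mean(
    conc: ConcentrationField, layout: TissueLayout, file_index: int, rows: slice
) -> float:
    f = layout.files[file_index]
    ids = [c.id for c in layout.cells if c.file_index == file_index]
    sub = conc.values[rows, f.col0 : f.col0 + f.width]
    owner = layout.cell_id_map[rows, f.col0 : f.col0 + f.width]
    mask = np.isin(owner, ids)
    if not mask.any():
        raise ObservableError("empty evaluation window")
    return float(sub[mask].mean())


def vm_minimum_ratio(conc: ConcentrationField, layout: TissueLayout) -> float:
    """Separation-layer / bordering-replum concentration ratio (< 1: minimum)."""
    return minimum_metrics(conc, layout).ratio_sep_replum


def minimum_metrics(conc: ConcentrationField, layout: TissueLayout) -> MinimumMetrics:
    strips = layout.vm_strips
    if not strips:
        raise ObservableError("layout has no VM strips")
    rows = layout.middle_third_rows()
    ratios = []
    seps = []
    reps = []
    for strip in strips:
        sep = _file_mean(conc, layout, _sep_file_of_strip(layout, strip).index, rows)
        rep = _file_mean(conc, layout, _bordering_replum_file(layout, strip).index, rows)
        if rep <= 0:
            raise ObservableError("zero replum concentration in evaluation window")
        ratios.append(sep / rep)
        seps.append(sep)
        reps.append(rep)
    valve_mean = conc.cell_type_mean(VALVE, rows=rows)
    return MinimumMetrics(
        ratio_sep_replum=float(np.mean(ratios)),
        sep_mean=float(np.mean(seps)),
        replum_mean=float(np.mean(reps)),
        valve_mean=valve_mean,
        per_strip_ratio=tuple(ratios),
    )


def vm_flux_metrics(flux: FluxField, layout: TissueLayout) -> FluxMetrics:
    """Cut-line flux sums at every VM strip, see :class:`FluxMetrics`."""
    strips = layout.vm_strips
    if not strips:
        raise ObservableError("layout has no VM strips")
    rows = layout.middle_third_rows()
    h = layout.h
    nets = []
    mags = []
    pars = []
    for strip in strips:
        files = [layout.files[fi] for fi in strip.file_indices]
        if len(files) == 2:
            # cut at the strip midline: average the two membrane interfaces
            # flanking the wall column between the VM files (mirror-symmetric)
            cut_cols = [files[1].wall_col - 1, files[1].wall_col]
        else:
            f = files[0]
            if f.width % 2 == 0:
                cut_cols = [f.col0 + f.width // 2 - 1]
            else:
                cut_cols = [f.col0 + f.width // 2 - 1, f.col0 + f.width // 2]
        sign = float(strip.toward_replum) or 1.0
        lines = [flux.flux_h[rows, c] * h for c in cut_cols]
        nets.append(sign * float(np.mean([ln.sum() for ln in lines])))
        mags.append(float(np.mean([np.abs(ln).sum() for ln in lines])))
        # parallel: basipetal flux through a horizontal cut at mid-window
        rb = (rows.start + rows.stop) // 2
        c0 = files[0].col0
        c1 = files[-1].col0 + files[-1].width
        pars.append(float(flux.flux_v[rb, c0:c1].sum()) * h)
    return FluxMetrics(
        transversal=float(np.mean(nets)),
        transversal_abs=float(np.mean(mags)),
        parallel=float(np.mean(pars)),
        per_strip_transversal=tuple(nets),
    )


# ----------------------------------------------------------------------
# scenario solving and sweeps


def solve_scenario(
    layout: TissueLayout,
    table: FacetStrengthTable,
    params: TransportParameters,
    settings: SolverSettings | None = None,
) -> tuple[ConcentrationField, FluxField]:
    """Steady state and fluxes of a scenario on a layout."""
    perms = assemble_permeabilities(layout, table, params)
    conc = steady_state(layout, perms, params, settings)
    flux = compute_fluxes(conc, layout, perms, params)
    return conc, flux


@dataclass
class SweepResult:
    """Minimum and flux metrics versus transporter strength.

    ``strengths`` is the swept multiplier of the scenario's tabled carrier
    strengths (1.0 = the default rate); metrics arrays are aligned to it.
    """

    scenario: str
    transporter: str
    cell_types: tuple[str, ...]
    strengths: np.ndarray
    ratio: np.ndarray
    sep_mean: np.ndarray
    replum_mean: np.ndarray
    valve_mean: np.ndarray
    transversal: np.ndarray
    transversal_abs: np.ndarray
    parallel: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strength": self.strengths,
                "ratio_sep_replum": self.ratio,
                "sep_mean": self.sep_mean,
                "replum_mean": self.replum_mean,
                "valve_mean": self.valve_mean,
                "transversal_flux": self.transversal,
                "transversal_flux_abs": self.transversal_abs,
                "parallel_flux": self.parallel,
            }
        )


def sweep_strength(
    table: FacetStrengthTable,
    transporter_label: str,
    cell_types: tuple[str, ...],
    strengths,
    layout: TissueLayout,
    params: TransportParameters,
    settings: SolverSettings | None = None,
) -> SweepResult:
    """One steady solve per strength multiplier; deterministic.

    ``strengths`` must be strictly increasing.  Every point records the
    minimum-depth and VM-flux metrics of the corresponding steady state.
    """
    strengths = np.asarray(list(strengths), dtype=float)
    if strengths.size == 0:
        raise ObservableError("empty strength grid")
    if np.any(strengths <= 0) or np.any(np.diff(strengths) <= 0):
        raise ObservableError("strength grid must be positive and strictly increasing")
    rows = {k: [] for k in ("ratio", "sep", "rep", "val", "tr", "trabs", "par")}
    for s in strengths:
        scaled = scale_transporter(table, transporter_label, cell_types, float(s))
        try:
            conc, flux = solve_scenario(layout, scaled, params, settings)
        except Exception as exc:
            raise ObservableError(f"solver failed at strength {s:g}: {exc}") from exc
        mm = minimum_metrics(conc, layout)
        fm = vm_flux_metrics(flux, layout)
        rows["ratio"].append(mm.ratio_sep_replum)
        rows["sep"].append(mm.sep_mean)
        rows["rep"].append(mm.replum_mean)
        rows["val"].append(mm.valve_mean)
        rows["tr"].append(fm.transversal)
        rows["trabs"].append(fm.transversal_abs)
        rows["par"].append(fm.parallel)
    return SweepResult(
        scenario=table.name,
        transporter=transporter_label,
        cell_types=tuple(cell_types),
        strengths=strengths,
        ratio=np.asarray(rows["ratio"]),
        sep_mean=np.asarray(rows["sep"]),
        replum_mean=np.asarray(rows["rep"]),
        valve_mean=np.asarray(rows["val"]),
        transversal=np.asarray(rows["tr"]),
        transversal_abs=np.asarray(rows["trabs"]),
        parallel=np.asarray(rows["par"]),
    )


def threshold_strength(
    sweep: SweepResult,
    threshold: float = 1.0,
) -> float | None:
    """Smallest swept strength at which the minimum ratio drops below
    ``threshold``, interpolated linearly in log-strength between the
    bracketing grid points; None if the criterion is never met.
    """
    if sweep.strengths.size == 0:
        raise ObservableError("empty sweep")
    r = sweep.ratio
    s = sweep.strengths
    below = r < threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(s[0])
    # log-linear interpolation of the crossing
    x0, x1 = np.log(s[i - 1]), np.log(s[i])
    y0, y1 = r[i - 1], r[i]
    t = (threshold - y0) / (y1 - y0)
    return float(np.exp(x0 + t * (x1 - x0)))


FLUX_PASSAGE = "flux_passage"
FLUX_BARRIER = "flux_barrier"


def classify_regime(sweep: SweepResult, min_abs_rho: float = 0.8) -> str:
    """Classify a sweep as flux-passage or flux-barrier.

    Uses the Spearman rank correlation between the minimum ratio and the
    transversal VM flux magnitude across the sweep: strongly negative
    (flux grows as the minimum deepens) means flux-passage; strongly
    positive means flux-barrier.  Weak or ambiguous correlation raises
    :class:`IndeterminateRegimeError`.
    """
    if sweep.strengths.size < 3:
        raise ObservableError("regime classification needs at least 3 sweep points")
    mag = np.abs(sweep.transversal)
    import warnings

    with warnings.catch_warnings():
        # a constant flux column is reported as indeterminate below
        warnings.simplefilter("ignore")
        rho = spearmanr(sweep.ratio, mag).statistic
    if not np.isfinite(rho):
        raise IndeterminateRegimeError("constant or degenerate flux/ratio relation")
    if rho <= -min_abs_rho:
        return FLUX_PASSAGE
    if rho >= min_abs_rho:
        return FLUX_BARRIER
    raise IndeterminateRegimeError(
        f"ambiguous flux/ratio relation (spearman rho = {rho:.2f})"
    )
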