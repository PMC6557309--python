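"""In-silico perturbation experiments.

Two computational experiments discriminate the flux-passage from the
flux-barrier regime:

* **VM ablation** — rendering a contiguous stretch of valve-margin cells
  totally impermeable (cell death), with every transporter pattern
  elsewhere kept fixed.  Under a flux-passage (efflux-driven) regime,
  obstructing the VM reroutes the transversal flux: auxin drops in the
  replum cells flanking the ablation and rises in the flanking valve
  cells.  Under a flux-barrier (import-driven) regime the same obstruction
  barely changes the flanking tissues.

* **Production/decay scan** — a classical reaction-diffusion alternative:
  identical basally polarized efflux in all cell types, auxin production
  confined to replum and valve, breakdown confined to the VM.  The scan
  finds the smallest decay amplification at which a noticeable minimum
  forms while staying confined to the VM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ABLATED, REPLUM, VALVE, WALL, TissueLayout
from .scenarios import (
    FacetStrengthTable,
    TransportParameters,
    assemble_permeabilities,
    conceptual_table,
)
from .solver import SolverSettings, per_type_map, steady_state
from .observables import _bordering_replum_file, minimum_metrics


class AblationError(ValueError):
    pass


class CriterionUnreachableError(RuntimeError):
    """The production/decay criterion is not met within the fold bracket."""

    def __init__(self, message: str, deepest_ratio: float):
        super().__init__(message)
        self.deepest_ratio = deepest_ratio


@dataclass(frozen=True)
class AblationSpec:
    """Which VM cells to kill.

    ``flanking_replum`` selects the two VM strips flanking the k-th replum;
    ``vm_strips`` selects explicit indices into ``layout.vm_strips``; "all"
    via ``vm_strips=None, flanking_replum=None``.  ``extent`` is the
    ablated fraction of the cell rows (a centred contiguous block);
    ``block_walls`` extends total impermeability to the ablated cells'
    bounding walls, preventing an apoplastic bypass through their wall
    channels.
    """

    flanking_replum: int | None = None
    vm_strips: tuple[int, ...] | None = None
    extent: float = 1.0
    block_walls: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.extent <= 1.0:
            raise AblationError("extent must be within [0, 1]")
        if self.flanking_replum is not None and self.vm_strips is not None:
            raise AblationError("give either flanking_replum or vm_strips, not both")


def _target_strips(layout: TissueLayout, spec: AblationSpec):
    vms = layout.vm_strips
    if spec.vm_strips is not None:
        if len(spec.vm_strips) == 0:
            raise AblationError("empty ablation target set")
        try:
            return [vms[i] for i in spec.vm_strips]
        except IndexError as exc:
            raise AblationError("VM strip index out of range") from exc
    if spec.flanking_replum is not None:
        sel = [s for s in vms if s.replum_strip == spec.flanking_replum]
        if not sel:
            raise AblationError(f"no VM strips flank replum {spec.flanking_replum}")
        return sel
    return list(vms)


def _ablated_rows(layout: TissueLayout, extent: float) -> range:
    n = layout.spec.rows
    n_abl = int(round(extent * n))
    lo = (n - n_abl) // 2
    return range(lo, lo + n_abl)


def apply_ablation(layout: TissueLayout, spec: AblationSpec) -> TissueLayout:
    """A copy of the layout with the targeted VM cells made impermeable.

    All cytosol sites of the targeted cells (and, by default, their
    bounding wall sites) become no-flux; transporter patterns elsewhere
    are untouched.  A zero-extent ablation returns an unchanged copy.
    """
    strips = _target_strips(layout, spec)
    rows = _ablated_rows(layout, spec.extent)
    new = TissueLayout(
        spec=layout.spec,
        class_map=layout.class_map.copy(),
        cell_id_map=layout.cell_id_map,
        cells=layout.cells,
        files=layout.files,
        strips=layout.strips,
    )
    if len(rows) == 0:
        return new
    file_ids = {fi for s in strips for fi in s.file_indices}
    cm = new.class_map
    for cell in layout.cells:
        if cell.file_index not in file_ids or cell.row_index not in rows:
            continue
        cm[cell.rows, cell.cols] = ABLATED
        if spec.block_walls:
            r0, r1 = cell.row0 - 1, cell.row0 + cell.height + 1
            # column range wraps at the periodic seam
            cols = np.arange(cell.col0 - 1, cell.col0 + cell.width + 1) % layout.ncols
            ring = cm[np.ix_(np.arange(r0, r1), cols)]
            ring[ring == WALL] = ABLATED
            cm[np.ix_(np.arange(r0, r1), cols)] = ring
    return new


@dataclass(frozen=True)
class AblationResponse:
    """Relative change of the tissues flanking the ablated VM strips.

    Means are taken over the middle-third row window of the replum file
    and the valve file directly adjacent to each ablated strip, averaged
    over the targeted strips.  Deltas are (after - before) / before.
    """

    replum_before: float
    replum_after: float
    valve_before: float
    valve_after: float

    @property
    def replum_delta(self) -> float:
        return (self.replum_after - self.replum_before) / self.replum_before

    @property
    def valve_delta(self) -> float:
        return (self.valve_after - self.valve_before) / self.valve_before

    def noticeable(self, threshold: float = 0.1) -> bool:
        """Whether either flanking tissue changed by more than ``threshold``."""
        return max(abs(self.replum_delta), abs(self.valve_delta)) > threshold


def _flanking_valve_file(layout: TissueLayout, strip):
    """The valve file adjacent to a VM strip, on its valve side."""
    away = -strip.toward_replum
    fids = strip.file_indices
    edge = layout.files[fids[0] if away < 0 else fids[-1]]
    nxt = (edge.index + away) % len(layout.files)
    f = layout.files[nxt]
    if f.cell_type != VALVE:
        raise AblationError("expected a valve file adjacent to the VM strip")
    return f


def ablation_response(
    table: FacetStrengthTable,
    spec: AblationSpec,
    layout: TissueLayout,
    params: TransportParameters,
    settings: SolverSettings | None = None,
) -> AblationResponse:
    """Paired steady solves before and after ablation."""
    from .observables import _file_mean  # local import to avoid cycle at import time

    strips = _target_strips(layout, spec)
    rows = layout.middle_third_rows()

    def tissue_means(lay: TissueLayout, conc) -> tuple[float, float]:
        reps, vals = [], []
        for s in strips:
            reps.append(_file_mean(conc, lay, _bordering_replum_file(lay, s).index, rows))
            vals.append(_file_mean(conc, lay, _flanking_valve_file(lay, s).index, rows))
        return float(np.mean(reps)), float(np.mean(vals))

    perms = assemble_permeabilities(layout, table, params)
    before = steady_state(layout, perms, params, settings)
    rep_b, val_b = tissue_means(layout, before)

    ablated = apply_ablation(layout, spec)
    perms_a = assemble_permeabilities(ablated, table, params)
    after = steady_state(ablated, perms_a, params, settings)
    rep_a, val_a = tissue_means(ablated, after)

    return AblationResponse(
        replum_before=rep_b, replum_after=rep_a,
        valve_before=val_b, valve_after=val_a,
    )


# ----------------------------------------------------------------------
# production/decay requirement


def _production_decay_maps(
    layout: TissueLayout, params: TransportParameters, fold: float
) -> tuple[np.ndarray, np.ndarray]:
    production = per_type_map(
        layout, 0.0, {REPLUM: params.production, VALVE: params.production}, default=0.0
    )
    vm_types = {ct: fold * params.decay for ct in ("separation_layer", "lignifying_layer", "vm_undivided")}
    decay = per_type_map(layout, 0.0, vm_types, default=0.0)
    return production, decay


def production_decay_metrics(
    layout: TissueLayout,
    params: TransportParameters,
    fold: float,
    settings: SolverSettings | None = None,
):
    """Minimum metrics of the production/decay scenario at one decay fold."""
    table = conceptual_table("production_decay")
    perms = assemble_permeabilities(layout, table, params)
    production, decay = _production_decay_maps(layout, params, fold)
    conc = steady_state(
        layout, perms, params, settings,
        production_map=production, decay_map=decay,
    )
    return minimum_metrics(conc, layout)


def production_decay_requirement(
    layout: TissueLayout,
    params: TransportParameters,
    ratio_target: float = 0.5,
    confinement_band: float = 0.25,
    max_fold: float = 1e12,
    settings: SolverSettings | None = None,
    log_tol: float = 0.05,
) -> float:
    """Smallest VM decay amplification producing a confined minimum.

    The criterion is a separation/replum ratio at or below ``ratio_target``
    while the valve and replum means stay within ``confinement_band`` of
    their fold-1 values (the minimum stays confined to the VM).  The fold
    is located by a coarse log-spaced scan followed by bisection in
    log-fold; deterministic.  Raises :class:`CriterionUnreachableError` if
    no fold up to ``max_fold`` satisfies the criterion.
    """
    ref = production_decay_metrics(layout, params, 1.0, settings)

    def ok(m) -> bool:
        return (
            m.ratio_sep_replum <= ratio_target
            and abs(m.valve_mean / ref.valve_mean - 1.0) <= confinement_band
            and abs(m.replum_mean / ref.replum_mean - 1.0) <= confinement_band
        )

    deepest = ref.ratio_sep_replum
    lo_exp, hi_exp = 0.0, float(np.log10(max_fold))
    exps = np.arange(lo_exp, hi_exp + 1e-9, 1.0)
    found = None
    prev = 0.0
    for e in exps:
        m = production_decay_metrics(layout, params, 10.0**e, settings)
        deepest = min(deepest, m.ratio_sep_replum)
        if ok(m):
            found = e
            break
        prev = e
    if found is None:
        raise CriterionUnreachableError(
            f"no confined minimum with ratio <= {ratio_target} up to fold {max_fold:g} "
            f"(deepest ratio reached: {deepest:.3g})",
            deepest_ratio=deepest,
        )
    if found == 0.0:
        return 1.0
    lo, hi = prev, found
    while hi - lo > log_tol:
        mid = 0.5 * (lo + hi)
        m = production_decay_metrics(layout, params, 10.0**mid, settings)
        if ok(m):
            hi = mid
        else:
            lo = mid
    return float(10.0**hi)
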