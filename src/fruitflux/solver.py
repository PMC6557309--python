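"""Auxin dynamics on the tissue lattice.

Per cytosol site, auxin obeys diffusion (D_cyt) plus homogeneous production
and first-order decay, an additional apical source in the topmost cell row
(style-derived auxin), and carrier-mediated membrane exchange with
adjacent wall sites; per wall (apoplast) site, diffusion (D_wall) plus the
opposing membrane exchange.  Exchange across a membrane interface is

    J_in(to cell) = P_in * a_wall - P_out * a_cyt        [conc um/s]

per unit interface length.  The basal wall row is held at concentration 0
(auxin freely leaves the organ basally); all other outer boundaries are
no-flux, and the circumferential axis wraps periodically.

The system is linear, so the steady state is obtained by a direct sparse
solve; an explicit forward-Euler integrator of the same balance equations
is kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CYT, WALL, TissueLayout
from .scenarios import PermeabilityField, TransportParameters


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings.

    ``mode`` selects the direct sparse solve (default) or explicit
    time-stepping.  ``dt`` must respect the diffusive stability bound
    h^2 / (4 max(D_cyt, D_wall)); None picks 90% of the bound.  ``tol`` is
    the steady-state criterion max |da/dt| / mean(a).
    """

    mode: str = "direct"
    dt: float | None = None
    tol: float = 1e-9
    max_iter: int = 50_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "explicit"):
            raise SolverError(f"unknown solver mode {self.mode!r}")
        if self.tol <= 0:
            raise SolverError("tol must be positive")


@dataclass
class ConcentrationField:
    """Per-site auxin concentration (arbitrary units); 0 on non-sites."""

    layout: TissueLayout
    values: np.ndarray
    residual: float = 0.0

    @property
    def cyt_mask(self) -> np.ndarray:
        return self.layout.class_map == CYT

    @property
    def wall_mask(self) -> np.ndarray:
        return self.layout.class_map == WALL

    def cell_type_mean(self, *cell_types: str, rows: slice | None = None) -> float:
        """Mean cytosolic concentration over cells of given types."""
        mask = np.isin(
            self.layout.cell_id_map,
            [c.id for c in self.layout.cells_of_type(*cell_types)],
        )
        if rows is not None:
            keep = np.zeros_like(mask)
            keep[rows] = True
            mask &= keep
        if not mask.any():
            raise SolverError(f"no cytosol sites for cell types {cell_types}")
        return float(self.values[mask].mean())


@dataclass
class FluxField:
    """Signed flux per lattice interface, in conc um/s per unit length.

    ``flux_h[r, c]`` is the flux crossing from site (r, c) to
    (r, (c+1) % ncols) (positive rightward); ``flux_v[r, c]`` the flux from
    (r, c) to (r+1, c) (positive basipetal / downward).  Both combine the
    diffusive (within-compartment) and membrane (carrier plus background)
    contributions; the boolean masks mark which interfaces are membrane
    crossings.  Reversing the orientation of an interface flips the sign.
    """

    layout: TissueLayout
    flux_h: np.ndarray
    flux_v: np.ndarray
    mem_h: np.ndarray
    mem_v: np.ndarray


@dataclass
class Operator:
    """Assembled linear system  da/dt = M a + src  over valid sites."""

    layout: TissueLayout
    M: sp.csr_matrix
    src: np.ndarray
    unknown_of_flat: np.ndarray  # -1 for excluded sites
    flat_of_unknown: np.ndarray
    dirichlet: np.ndarray        # unknown indices held at 0 (basal exit)

    def to_grid(self, vec: np.ndarray) -> np.ndarray:
        g = np.zeros(self.layout.nrows * self.layout.ncols)
        g[self.flat_of_unknown] = vec
        return g.reshape(self.layout.nrows, self.layout.ncols)

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        return grid.reshape(-1)[self.flat_of_unknown]


def _default_maps(
    layout: TissueLayout, params: TransportParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site production, decay and apical-source maps from scalars."""
    cyt = layout.class_map == CYT
    production = np.where(cyt, params.production, 0.0)
    decay = np.where(cyt, params.decay, 0.0)
    apical = np.zeros(layout.class_map.shape)
    band = layout.cell_row_sites(layout.apical_cell_row)
    apical[band] = np.where(cyt[band], params.apical_source, 0.0)
    return production, decay, apical


def build_operator(
    layout: TissueLayout,
    perms: PermeabilityField,
    params: TransportParameters,
    production_map: np.ndarray | None = None,
    decay_map: np.ndarray | None = None,
) -> Operator:
    """Assemble the sparse balance operator  da/dt = M a + src."""
    nr, nc = layout.nrows, layout.ncols
    h = layout.h
    cls = layout.class_map
    adj = layout.adjacency()

    valid = (cls == CYT) | (cls == WALL)
    flat_of_unknown = np.nonzero(valid.reshape(-1))[0]
    unknown_of_flat = np.full(nr * nc, -1, dtype=np.int64)
    unknown_of_flat[flat_of_unknown] = np.arange(flat_of_unknown.size)
    n = flat_of_unknown.size

    rows_list: list[np.ndarray] = []
    cols_list: list[np.ndarray] = []
    vals_list: list[np.ndarray] = []

    def add_pairs(i_flat: np.ndarray, j_flat: np.ndarray, g: np.ndarray) -> None:
        """Symmetric exchange: da_i/dt += g (a_j - a_i), same for j."""
        ui = unknown_of_flat[i_flat]
        uj = unknown_of_flat[j_flat]
        rows_list.extend([ui, ui, uj, uj])
        cols_list.extend([uj, ui, ui, uj])
        vals_list.extend([g, -g, g, -g])

    cols_idx = np.arange(nc)
    # horizontal diffusion pairs
    for kind, D in ((1, params.D_cyt), (2, params.D_wall)):
        rr, cc = np.nonzero(adj.h_kind == kind)
        i_flat = rr * nc + cc
        j_flat = rr * nc + (cc + 1) % nc
        add_pairs(i_flat, j_flat, np.full(rr.size, D / h**2))
    # vertical diffusion pairs
    for kind, D in ((1, params.D_cyt), (2, params.D_wall)):
        rr, cc = np.nonzero(adj.v_kind == kind)
        i_flat = rr * nc + cc
        j_flat = (rr + 1) * nc + cc
        add_pairs(i_flat, j_flat, np.full(rr.size, D / h**2))

    # membrane exchange: cytosol gains P_in a_w - P_out a_c (rate / h)
    uc = unknown_of_flat[adj.mem_cyt_flat]
    uw = unknown_of_flat[adj.mem_wall_flat]
    pin = perms.P_in / h
    pout = perms.P_out / h
    rows_list.extend([uc, uc, uw, uw])
    cols_list.extend([uw, uc, uc, uw])
    vals_list.extend([pin, -pout, pout, -pin])

    production, decay, apical = _default_maps(layout, params)
    if production_map is not None:
        production = production_map
    if decay_map is not None:
        decay = decay_map

    # decay on the diagonal
    cyt_flat = np.nonzero((cls == CYT).reshape(-1))[0]
    u_cyt = unknown_of_flat[cyt_flat]
    rows_list.append(u_cyt)
    cols_list.append(u_cyt)
    vals_list.append(-decay.reshape(-1)[cyt_flat])

    src = (production + apical).reshape(-1)[flat_of_unknown]

    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    vals = np.concatenate(vals_list)

    # basal Dirichlet: bottom wall row held at zero concentration
    if params.basal_open:
        basal_flat = layout.basal_row * nc + cols_idx
        basal_flat = basal_flat[valid.reshape(-1)[basal_flat]]
        dirichlet = unknown_of_flat[basal_flat]
        is_dir = np.zeros(n, dtype=bool)
        is_dir[dirichlet] = True
        keep = ~is_dir[rows]
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
        src[dirichlet] = 0.0
        # identity equations a = 0 for the basal exit row
        rows = np.concatenate([rows, dirichlet])
        cols = np.concatenate([cols, dirichlet])
        vals = np.concatenate([vals, np.ones(dirichlet.size)])
    else:
        dirichlet = np.empty(0, dtype=np.int64)

    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Operator(
        layout=layout,
        M=M,
        src=src,
        unknown_of_flat=unknown_of_flat,
        flat_of_unknown=flat_of_unknown,
        dirichlet=dirichlet,
    )


def steady_state(
    layout: TissueLayout,
    perms: PermeabilityField,
    params: TransportParameters,
    settings: SolverSettings | None = None,
    production_map: np.ndarray | None = None,
    decay_map: np.ndarray | None = None,
) -> ConcentrationField:
    """Steady state of the transport system.

    A steady state exists (and is unique) whenever there is decay or an
    open basal boundary; otherwise the system is singular and an error is
    raised.  The direct mode solves the sparse linear system exactly; the
    explicit mode integrates the same equations to the stated tolerance.
    """
    settings = settings or SolverSettings()
    if not params.basal_open and params.decay == 0 and decay_map is None:
        raise SolverError(
            "no decay and no open basal boundary: steady state is not unique"
        )
    op = build_operator(layout, perms, params, production_map, decay_map)

    if settings.mode == "direct":
        try:
            a = spla.spsolve(op.M.tocsc(), -op.src)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise SolverError(f"sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(a)):
            raise SolverError("singular steady-state system")
        rate = op.M @ a + op.src
        if op.dirichlet.size:
            rate[op.dirichlet] = 0.0
        mean = float(np.abs(a).mean()) or 1.0
        residual = float(np.abs(rate).max()) / mean
        return ConcentrationField(layout=layout, values=op.to_grid(a), residual=residual)

    # explicit mode: integrate until |da/dt| is small relative to the mean
    a = np.zeros(op.M.shape[0])
    dt = _stable_dt(layout, params, op, settings.dt)
    for it in range(settings.max_iter):
        rate = op.M @ a + op.src
        if op.dirichlet.size:
            rate[op.dirichlet] = 0.0
        a += dt * rate
        if it % 200 == 0:
            mean = float(np.abs(a).mean()) or 1.0
            if float(np.abs(rate).max()) / mean < settings.tol:
                break
    else:
        raise SolverError("explicit steady state did not converge")
    mean = float(np.abs(a).mean()) or 1.0
    residual = float(np.abs(rate).max()) / mean
    return ConcentrationField(layout=layout, values=op.to_grid(a), residual=residual)


def _stable_dt(
    layout: TissueLayout,
    params: TransportParameters,
    op: Operator,
    dt: float | None,
) -> float:
    bound = layout.h**2 / (4.0 * max(params.D_cyt, params.D_wall))
    if dt is not None:
        if dt > bound * (1 + 1e-12):
            raise SolverError(
                f"dt={dt} violates the diffusive stability bound {bound:g} s"
            )
        return dt
    # also keep every local rate constant stable (membrane terms, decay)
    diag_bound = 0.9 / float(np.abs(op.M.diagonal()).max())
    return min(0.9 * bound, diag_bound)


def integrate(
    layout: TissueLayout,
    perms: PermeabilityField,
    params: TransportParameters,
    initial: ConcentrationField,
    t_end: float,
    settings: SolverSettings | None = None,
    production_map: np.ndarray | None = None,
    decay_map: np.ndarray | None = None,
) -> ConcentrationField:
    """Explicit forward-time integration over ``t_end`` seconds.

    Under the stability bound the update preserves nonnegativity of the
    field.  Used as an independent cross-check of the direct solver.
    """
    settings = settings or SolverSettings(mode="explicit")
    op = build_operator(layout, perms, params, production_map, decay_map)
    dt = _stable_dt(layout, params, op, settings.dt)
    a = op.from_grid(initial.values)
    t = 0.0
    rate = op.M @ a + op.src
    while t < t_end - 1e-12:
        step = min(dt, t_end - t)
        rate = op.M @ a + op.src
        if op.dirichlet.size:
            rate[op.dirichlet] = 0.0
        a += step * rate
        t += step
    mean = float(np.abs(a).mean()) or 1.0
    residual = float(np.abs(rate).max()) / mean
    return ConcentrationField(layout=layout, values=op.to_grid(a), residual=residual)


def compute_fluxes(
    conc: ConcentrationField,
    layout: TissueLayout,
    perms: PermeabilityField,
    params: TransportParameters,
) -> FluxField:
    """Per-interface signed fluxes of a concentration field.

    Diffusive flux between same-compartment neighbours follows Fick's law,
    -D * (a_j - a_i) / h; membrane interfaces carry the carrier/background
    exchange P_out a_cyt - P_in a_wall (oriented out of the cytosol).
    """
    adj = layout.adjacency()
    h = layout.h
    a = conc.values
    nr, nc = a.shape

    a_right = np.roll(a, -1, axis=1)
    flux_h = np.zeros((nr, nc))
    flux_h[adj.h_kind == 1] = (params.D_cyt / h) * (a - a_right)[adj.h_kind == 1]
    flux_h[adj.h_kind == 2] = (params.D_wall / h) * (a - a_right)[adj.h_kind == 2]

    flux_v = np.zeros((nr - 1, nc))
    dv = a[:-1, :] - a[1:, :]
    flux_v[adj.v_kind == 1] = (params.D_cyt / h) * dv[adj.v_kind == 1]
    flux_v[adj.v_kind == 2] = (params.D_wall / h) * dv[adj.v_kind == 2]

    a_flat = a.reshape(-1)
    outward = perms.P_out * a_flat[adj.mem_cyt_flat] - perms.P_in * a_flat[adj.mem_wall_flat]
    crossing = np.where(adj.mem_cyt_first, outward, -outward)
    hz = adj.mem_horizontal
    flux_h[adj.mem_r[hz], adj.mem_c[hz]] = crossing[hz]
    flux_v[adj.mem_r[~hz], adj.mem_c[~hz]] = crossing[~hz]

    return FluxField(
        layout=layout,
        flux_h=flux_h,
        flux_v=flux_v,
        mem_h=(adj.h_kind == 3) | (adj.h_kind == 4),
        mem_v=(adj.v_kind == 3) | (adj.v_kind == 4),
    )


def mass_budget(
    conc: ConcentrationField,
    flux: FluxField,
    layout: TissueLayout,
    params: TransportParameters,
    production_map: np.ndarray | None = None,
    decay_map: np.ndarray | None = None,
) -> dict[str, float]:
    """Integrated auxin budget, in conc um^2/s.

    At steady state production + apical input balances decay + basal
    efflux; ``net`` reports the imbalance.
    """
    h = layout.h
    production, decay, apical = _default_maps(layout, params)
    if production_map is not None:
        production = production_map
    if decay_map is not None:
        decay = decay_map
    area = h * h
    prod_total = float(production.sum()) * area
    apical_total = float(apical.sum()) * area
    decay_total = float((decay * conc.values).sum()) * area
    if params.basal_open:
        basal_total = float(flux.flux_v[layout.basal_row - 1, :].sum()) * h
    else:
        basal_total = 0.0
    net = prod_total + apical_total - decay_total - basal_total
    return {
        "production": prod_total,
        "apical_input": apical_total,
        "decay": decay_total,
        "basal_efflux": basal_total,
        "net": net,
    }


def per_type_map(
    layout: TissueLayout,
    base: float,
    per_type: Mapping[str, float],
    default: float | None = None,
) -> np.ndarray:
    """Per-site cytosol rate map with per-cell-type overrides.

    ``base`` applies to cell types not listed; pass ``default=0`` to
    restrict the rate to the listed types only.
    """
    cyt = layout.class_map == CYT
    fill = base if default is None else default
    out = np.where(cyt, fill, 0.0)
    for ct, val in per_type.items():
        ids = [c.id for c in layout.cells_of_type(ct)]
        mask = np.isin(layout.cell_id_map, ids)
        out[mask] = val
    return out
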