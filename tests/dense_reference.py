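"""Independent dense reference solver for the transport balance equations.

Deliberately naive: loops over every site and neighbour, builds the dense
balance matrix from the stated equations and solves with numpy.  Shares no
assembly code with the package solver; membrane permeabilities are
recomputed here from the facet tables via ``facet_segments``.
"""

import numpy as np

from fruitflux.geometry import CYT, WALL, facet_segments, FACETS


def dense_steady_state(layout, table, params, production_map=None, decay_map=None):
    """Steady state by brute-force dense linear solve, as a grid array."""
    cls = layout.class_map
    nr, nc = cls.shape
    h = layout.h

    sites = [(r, c) for r in range(nr) for c in range(nc) if cls[r, c] in (WALL, CYT)]
    index = {rc: i for i, rc in enumerate(sites)}
    n = len(sites)
    A = np.zeros((n, n))
    b = np.zeros(n)

    # membrane permeabilities per (cyt, wall) site pair
    pin_of = {}
    pout_of = {}
    for cell in layout.cells:
        if cls[cell.row0, cell.col0] != CYT:
            continue  # ablated cell
        segs = facet_segments(layout, cell.id)
        for facet, pairs in segs.items():
            lax = table.strength(cell.cell_type, "LAX1", facet)
            pin3 = table.strength(cell.cell_type, "PIN3", facet)
            pin7 = table.strength(cell.cell_type, "PIN7", facet)
            p_in = params.P_bg_in + params.P_LAX_max * lax
            p_out = params.P_bg_eff + params.P_PIN_max * (pin3 + pin7)
            for (cr, cc, wr, wc) in pairs:
                pin_of[(cr, cc, wr, wc)] = p_in
                pout_of[(cr, cc, wr, wc)] = p_out

    ch = layout.spec.sites(layout.spec.height)
    top_band = range(1, 1 + ch)

    for (r, c) in sites:
        i = index[(r, c)]
        me = cls[r, c]
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            r2, c2 = r + dr, (c + dc) % nc
            if not (0 <= r2 < nr):
                continue
            other = cls[r2, c2]
            if other not in (WALL, CYT):
                continue
            j = index[(r2, c2)]
            if me == other:
                D = params.D_cyt if me == CYT else params.D_wall
                A[i, j] += D / h**2
                A[i, i] -= D / h**2
            elif me == CYT:
                key = (r, c, r2, c2)
                A[i, i] -= pout_of[key] / h
                A[i, j] += pin_of[key] / h
            else:
                key = (r2, c2, r, c)
                A[i, i] -= pin_of[key] / h
                A[i, j] += pout_of[key] / h
        if me == CYT:
            d = params.decay if decay_map is None else decay_map[r, c]
            p = params.production if production_map is None else production_map[r, c]
            A[i, i] -= d
            b[i] += p
            if r in top_band:
                b[i] += params.apical_source

    if params.basal_open:
        for c in range(nc):
            if (layout.basal_row, c) in index:
                i = index[(layout.basal_row, c)]
                A[i, :] = 0.0
                A[i, i] = 1.0
                b[i] = 0.0

    a = np.linalg.solve(A, -b)
    grid = np.zeros((nr, nc))
    for (r, c), i in index.items():
        grid[r, c] = a[i]
    return grid
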