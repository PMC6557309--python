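"""Tissue geometry: the flattened cylindrical fruit epidermis as a 2D grid.

The outer epidermis of the Arabidopsis fruit is modeled as a cylinder of
rectangular cells, unrolled into a 2D lattice that is periodic in the
circumferential direction.  Going around the ring the tissue order is

    valve - VM - replum - VM - valve - VM - replum - VM

where each valve-margin (VM) strip consists of a lignifying-layer file
(valve-proximal) and a separation-layer file (replum-proximal) from stage 16
onward, or of a single undivided file at stage 15, before the asymmetric
division that creates the two layers.

The lattice resolves subcellular detail: every cell is a rectangle of
cytosol sites surrounded by a one-site cell-wall (apoplast) layer shared
with its neighbours.  Row 0 is the apical end (towards the style); the
bottom wall row is the basal boundary where auxin can leave the organ.

Each cell's plasma membrane is partitioned into eight named facets
(upper-outer, upper-inner, inner-upper, inner-lower, lower-inner,
lower-outer, outer-lower, outer-upper), the granularity at which carrier
strengths are specified.  "Inner" is the lateral side facing the nearest
replum midline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import numpy as np

# site classification codes
EXTERIOR = 0
WALL = 1
CYT = 2
ABLATED = 3

# cell types
VALVE = "valve"
REPLUM = "replum"
SEPARATION = "separation_layer"
LIGNIFYING = "lignifying_layer"
VM_UNDIVIDED = "vm_undivided"

CELL_TYPES = (VALVE, REPLUM, SEPARATION, LIGNIFYING, VM_UNDIVIDED)
#: cell types composing a valve margin strip
VM_TYPES = (SEPARATION, LIGNIFYING, VM_UNDIVIDED)

#: canonical facet order, matching the carrier-strength table columns
FACETS = (
    "upper_outer",
    "upper_inner",
    "inner_upper",
    "inner_lower",
    "lower_inner",
    "lower_outer",
    "outer_lower",
    "outer_upper",
)
FACET_INDEX = {name: i for i, name in enumerate(FACETS)}

STAGES = ("15", "16", "17b", "custom")


class LayoutError(ValueError):
    """Raised for invalid layout specifications or queries."""


@dataclass(frozen=True)
class LayoutSpec:
    """Parameters defining a tissue layout.

    Dimensions are in micrometres and must be integer multiples of the grid
    spacing ``h``.  ``rows`` is the number of cell rows along the
    apical-basal axis (shared by every tissue; all cells in a layout have
    the same height so cell walls align into a regular lattice).  The
    default cell height is 40 um for stages 16/17b and 20 um for the
    younger stage-15 fruit, whose cells have not yet elongated; stage-15 VM
    cells therefore have a higher perimeter-to-area ratio than their
    stage-17b counterparts.
    """

    stage: str = "17b"
    rows: int = 20
    valve_files: int = 8
    replum_files: int = 3
    valve_width: float = 30.0
    replum_width: float = 20.0
    vm_width: float = 10.0
    cell_height: float | None = None  # None -> stage default
    h: float = 2.0
    vm_divided: bool | None = None  # None -> stage default; used for "custom"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise LayoutError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "custom" and self.vm_divided is None:
            raise LayoutError("stage 'custom' requires an explicit vm_divided flag")
        if self.rows < 1 or self.valve_files < 1 or self.replum_files < 1:
            raise LayoutError("rows and file counts must be >= 1")
        if self.h <= 0:
            raise LayoutError("grid spacing h must be positive")
        for name in ("valve_width", "replum_width", "vm_width", "height"):
            v = self.height if name == "height" else getattr(self, name)
            if v <= 0:
                raise LayoutError(f"{name} must be positive")
            sites = v / self.h
            if abs(sites - round(sites)) > 1e-9 or round(sites) < 1:
                raise LayoutError(
                    f"{name}={v} um is not a positive integer multiple of h={self.h} um"
                )

    @property
    def divided(self) -> bool:
        """Whether the VM has undergone the asymmetric cell division."""
        if self.vm_divided is not None:
            return self.vm_divided
        return self.stage != "15"

    @property
    def height(self) -> float:
        """Cell height in micrometres."""
        if self.cell_height is not None:
            return self.cell_height
        return 20.0 if self.stage == "15" else 40.0

    def sites(self, um: float) -> int:
        return int(round(um / self.h))


@dataclass(frozen=True)
class Cell:
    """One cell: a rectangle of cytosol sites (half-open in site indices)."""

    id: int
    cell_type: str
    file_index: int
    row_index: int
    row0: int
    col0: int
    width: int   # cytosol extent in sites (circumferential)
    height: int  # cytosol extent in sites (apical-basal)

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.height)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.width)


@dataclass(frozen=True)
class FileInfo:
    """One circumferential cell file (a column of cells of one type)."""

    index: int
    cell_type: str
    strip_index: int
    wall_col: int   # the wall column on the file's left
    col0: int       # first cytosol column
    width: int      # cytosol width in sites
    inner_is_left: bool


@dataclass(frozen=True)
class StripInfo:
    """A contiguous run of files of one tissue (valve / replum / VM)."""

    index: int
    tissue: str                 # "valve" | "replum" | "vm"
    file_indices: tuple[int, ...]
    replum_strip: int | None    # for VM strips: index of adjacent replum strip
    toward_replum: int          # for VM strips: +1 replum to the right, -1 left


@dataclass
class TissueLayout:
    """The discretized tissue: site classes, cell registry, facet index.

    ``class_map`` holds per-site classification (WALL / CYT / ABLATED),
    ``cell_id_map`` the owning cell of each cytosol site (-1 elsewhere).
    The circumferential (column) axis is periodic: the last column is a
    neighbour of column 0.
    """

    spec: LayoutSpec
    class_map: np.ndarray
    cell_id_map: np.ndarray
    cells: list[Cell]
    files: list[FileInfo]
    strips: list[StripInfo]
    _adjacency: "Adjacency | None" = field(default=None, repr=False)

    # -- basic geometry ------------------------------------------------
    @property
    def h(self) -> float:
        return self.spec.h

    @property
    def nrows(self) -> int:
        return int(self.class_map.shape[0])

    @property
    def ncols(self) -> int:
        return int(self.class_map.shape[1])

    @property
    def basal_row(self) -> int:
        """Site row of the basal wall (the open exit towards the plant)."""
        return self.nrows - 1

    @property
    def apical_cell_row(self) -> int:
        """Cell-row index receiving the style-derived apical source."""
        return 0

    def cell(self, cell_id: int) -> Cell:
        if not 0 <= cell_id < len(self.cells):
            raise LayoutError(f"unknown cell id {cell_id}")
        return self.cells[cell_id]

    def cells_of_type(self, *cell_types: str) -> list[Cell]:
        return [c for c in self.cells if c.cell_type in cell_types]

    @property
    def vm_strips(self) -> list[StripInfo]:
        return [s for s in self.strips if s.tissue == "vm"]

    def cell_row_sites(self, cell_row: int) -> slice:
        """Site-row slice of the cytosol band of one cell row."""
        ch = self.spec.sites(self.spec.height)
        r0 = 1 + cell_row * (ch + 1)
        return slice(r0, r0 + ch)

    def middle_third_rows(self) -> slice:
        """Site rows of the middle third of the cell rows.

        Used as the evaluation window for tissue-level summary statistics,
        away from the apical source and the basal sink.
        """
        n = self.spec.rows
        lo = n // 3
        hi = max(lo + 1, (2 * n) // 3)
        ch = self.spec.sites(self.spec.height)
        return slice(1 + lo * (ch + 1), 1 + (hi - 1) * (ch + 1) + ch)

    # -- adjacency / facet structure -----------------------------------
    def adjacency(self) -> "Adjacency":
        if self._adjacency is None:
            self._adjacency = _build_adjacency(self)
        return self._adjacency

    def invalidate_adjacency(self) -> None:
        self._adjacency = None

    # -- symmetry helpers ----------------------------------------------
    def mirror_column_map(self, replum_strip: int = 0) -> np.ndarray:
        """Column permutation of the mirror reflection about a replum midline.

        Returns an array ``m`` with ``m[c]`` the column that site column
        ``c`` maps to under the reflection.  The layout is bilaterally
        symmetric about every replum (and valve) midline, so applying the
        permutation to ``class_map`` leaves it unchanged.
        """
        reps = [s for s in self.strips if s.tissue == "replum"]
        strip = reps[replum_strip]
        f_lo = self.files[strip.file_indices[0]]
        f_hi = self.files[strip.file_indices[-1]]
        # twice the mirror-axis position: the strip's left wall column must
        # map onto the wall column right of the strip
        axis2 = f_lo.wall_col + (f_hi.col0 + f_hi.width)
        cols = np.arange(self.ncols)
        return (axis2 - cols) % self.ncols

    @property
    def ring_period(self) -> int:
        """Circumferential period in columns (half the ring: V-VM-R-VM)."""
        return self.ncols // 2

    # -- export ---------------------------------------------------------
    def to_text(self) -> str:
        """Site-classification matrix as a plain-text integer grid."""
        return "\n".join(" ".join(str(int(v)) for v in row) for row in self.class_map)

    def registry_json(self) -> str:
        cells = [
            {
                "id": c.id,
                "type": c.cell_type,
                "file": c.file_index,
                "row": c.row_index,
                "row0": c.row0,
                "col0": c.col0,
                "width": c.width,
                "height": c.height,
            }
            for c in self.cells
        ]
        meta = {
            "stage": self.spec.stage,
            "h_um": self.spec.h,
            "nrows": self.nrows,
            "ncols": self.ncols,
            "cells": cells,
        }
        return json.dumps(meta, indent=1)


@dataclass
class Adjacency:
    """Lattice adjacency, classified per neighbouring site pair.

    ``h_kind[r, c]`` classifies the horizontal pair ``(r, c)-(r, (c+1) % ncols)``
    and ``v_kind[r, c]`` the vertical pair ``(r, c)-(r+1, c)``:
    0 none (an ablated/exterior partner), 1 cytosol-cytosol,
    2 wall-wall, 3 membrane with the cytosol site first, 4 membrane with the
    cytosol site second.  Membrane interfaces are additionally listed in
    flat arrays carrying the owning cell, its facet, and the pair location.
    """

    h_kind: np.ndarray
    v_kind: np.ndarray
    # membrane interface arrays (one entry per cytosol-wall site pair)
    mem_cyt_flat: np.ndarray   # flat index of the cytosol site
    mem_wall_flat: np.ndarray  # flat index of the wall site
    mem_cell: np.ndarray       # owning cell id
    mem_facet: np.ndarray      # facet code 0..7
    mem_horizontal: np.ndarray  # True if the pair is horizontal
    mem_r: np.ndarray          # pair location (r, c) in h_kind / v_kind
    mem_c: np.ndarray
    mem_cyt_first: np.ndarray  # True if the cytosol site comes first in the pair

    @property
    def n_membrane(self) -> int:
        return int(self.mem_cyt_flat.size)


# ----------------------------------------------------------------------
# construction


def _ring_files(spec: LayoutSpec) -> list[tuple[str, int]]:
    """The circumferential file sequence as (cell_type, strip_index) pairs."""
    seq: list[tuple[str, int]] = []
    strip = 0
    for half in range(2):
        seq += [(VALVE, strip)] * spec.valve_files
        strip += 1
        seq += [(LIGNIFYING, strip), (SEPARATION, strip)] if spec.divided else [
            (VM_UNDIVIDED, strip)
        ]
        strip += 1
        seq += [(REPLUM, strip)] * spec.replum_files
        strip += 1
        seq += [(SEPARATION, strip), (LIGNIFYING, strip)] if spec.divided else [
            (VM_UNDIVIDED, strip)
        ]
        strip += 1
    return seq


def _width_sites(spec: LayoutSpec, cell_type: str) -> int:
    if cell_type == VALVE:
        return spec.sites(spec.valve_width)
    if cell_type == REPLUM:
        return spec.sites(spec.replum_width)
    return spec.sites(spec.vm_width)


def build_layout(spec: LayoutSpec) -> TissueLayout:
    """Build the periodic tissue lattice from a specification.

    The resulting layout satisfies the structural invariants: the eight-strip
    periodic tissue order with VM strips flanking each replum on both sides,
    bilateral mirror symmetry about every replum and valve midline, walls of
    one-site thickness separating all cells, and every cytosol site owned by
    exactly one cell.
    """
    ring = _ring_files(spec)
    ch = spec.sites(spec.height)
    nrows = 1 + spec.rows * (ch + 1)

    widths = [_width_sites(spec, t) for t, _ in ring]
    ncols = sum(w + 1 for w in widths)

    class_map = np.full((nrows, ncols), WALL, dtype=np.uint8)
    cell_id_map = np.full((nrows, ncols), -1, dtype=np.int32)

    files: list[FileInfo] = []
    cells: list[Cell] = []
    col = 0
    for fi, ((ctype, strip_idx), w) in enumerate(zip(ring, widths)):
        wall_col = col
        col0 = col + 1
        files.append(
            FileInfo(
                index=fi,
                cell_type=ctype,
                strip_index=strip_idx,
                wall_col=wall_col,
                col0=col0,
                width=w,
                inner_is_left=False,  # fixed below
            )
        )
        for cr in range(spec.rows):
            r0 = 1 + cr * (ch + 1)
            cid = len(cells)
            cells.append(
                Cell(
                    id=cid,
                    cell_type=ctype,
                    file_index=fi,
                    row_index=cr,
                    row0=r0,
                    col0=col0,
                    width=w,
                    height=ch,
                )
            )
            class_map[r0 : r0 + ch, col0 : col0 + w] = CYT
            cell_id_map[r0 : r0 + ch, col0 : col0 + w] = cid
        col = col0 + w

    # strips
    n_strips = ring[-1][1] + 1
    strip_files: list[list[int]] = [[] for _ in range(n_strips)]
    for f in files:
        strip_files[f.strip_index].append(f.index)
    tissue_of_strip = []
    for si in range(n_strips):
        ctype = files[strip_files[si][0]].cell_type
        tissue_of_strip.append(
            "valve" if ctype == VALVE else "replum" if ctype == REPLUM else "vm"
        )
    replum_strips = [i for i, t in enumerate(tissue_of_strip) if t == "replum"]

    # replum midline positions in column units (centre of the strip)
    def strip_center(si: int) -> float:
        fids = strip_files[si]
        lo = files[fids[0]].wall_col
        hi = files[fids[-1]].col0 + files[fids[-1]].width
        return (lo + hi) / 2.0

    rep_centers = [strip_center(si) for si in replum_strips]

    strips: list[StripInfo] = []
    for si in range(n_strips):
        replum_strip = None
        toward = 0
        if tissue_of_strip[si] == "vm":
            # the adjacent replum strip (VM strips always flank a replum)
            left = (si - 1) % n_strips
            right = (si + 1) % n_strips
            if tissue_of_strip[right] == "replum":
                replum_strip = replum_strips.index(right)
                toward = +1
            elif tissue_of_strip[left] == "replum":
                replum_strip = replum_strips.index(left)
                toward = -1
        strips.append(
            StripInfo(
                index=si,
                tissue=tissue_of_strip[si],
                file_indices=tuple(strip_files[si]),
                replum_strip=replum_strip,
                toward_replum=toward,
            )
        )

    # per-file inner orientation: towards the nearest replum midline
    for i, f in enumerate(files):
        center = f.wall_col + (1 + f.width) / 2.0
        best = None
        for rc in rep_centers:
            delta = rc - center
            delta -= round(delta / ncols) * ncols  # wrap to (-ncols/2, ncols/2]
            if best is None or abs(delta) < abs(best):
                best = delta
        # ties (a replum's own middle file) resolve to "inner on the left"
        inner_left = best is not None and (best < 0 or abs(best) < 1e-9)
        files[i] = replace(f, inner_is_left=inner_left)

    return TissueLayout(
        spec=spec,
        class_map=class_map,
        cell_id_map=cell_id_map,
        cells=cells,
        files=files,
        strips=strips,
    )


# ----------------------------------------------------------------------
# facets


def _facet_of(layout: TissueLayout, cell: Cell, direction: str, r: int, c: int) -> int:
    """Facet code of the membrane interface at cytosol site (r, c).

    ``direction`` is where the adjoining wall lies relative to the cytosol
    site.  The half split gives the extra site of an odd-length side to the
    inner (respectively upper) half, which keeps facet assignment
    mirror-symmetric.
    """
    f = layout.files[cell.file_index]
    inner_left = f.inner_is_left
    if direction in ("up", "down"):
        side = "upper" if direction == "up" else "lower"
        t = c - cell.col0
        n_inner = (cell.width + 1) // 2
        in_inner = t < n_inner if inner_left else t >= cell.width - n_inner
        half = "inner" if in_inner else "outer"
    else:
        is_left = direction == "left"
        side = "inner" if (is_left == inner_left) else "outer"
        t = r - cell.row0
        n_upper = (cell.height + 1) // 2
        half = "upper" if t < n_upper else "lower"
    return FACET_INDEX[f"{side}_{half}"]


def facet_segments(layout: TissueLayout, cell_id: int) -> dict[str, list[tuple[int, int, int, int]]]:
    """Membrane interface sites of one cell, grouped by facet.

    Returns ``{facet: [(cyt_r, cyt_c, wall_r, wall_c), ...]}``.  The eight
    facets partition the cell's membrane interface sites; the two halves of
    every side are equal in length up to one site.  Interfaces whose wall
    partner has been ablated are omitted.
    """
    cell = layout.cell(cell_id)
    nc = layout.ncols
    segs: dict[str, list[tuple[int, int, int, int]]] = {f: [] for f in FACETS}

    def add(direction: str, r: int, c: int, wr: int, wc: int) -> None:
        if layout.class_map[wr, wc] != WALL:
            return
        segs[FACETS[_facet_of(layout, cell, direction, r, c)]].append((r, c, wr, wc))

    for c in range(cell.col0, cell.col0 + cell.width):
        add("up", cell.row0, c, cell.row0 - 1, c)
        add("down", cell.row0 + cell.height - 1, c, cell.row0 + cell.height, c)
    for r in range(cell.row0, cell.row0 + cell.height):
        add("left", r, cell.col0, r, (cell.col0 - 1) % nc)
        add("right", r, cell.col0 + cell.width - 1, r, (cell.col0 + cell.width) % nc)
    return segs


def perimeter_area_ratio(layout: TissueLayout, cell_id: int) -> float:
    """Membrane length over cytosol area of a cell, in 1/um.

    Early-stage VM cells are smaller and thus have a higher ratio, gaining
    relatively more auxin through the chemiosmotically biased background
    influx.
    """
    cell = layout.cell(cell_id)
    h = layout.h
    w_um, h_um = cell.width * h, cell.height * h
    return 2.0 * (w_um + h_um) / (w_um * h_um)


# ----------------------------------------------------------------------
# adjacency construction


def _build_adjacency(layout: TissueLayout) -> Adjacency:
    cls = layout.class_map
    nr, nc = cls.shape

    left = cls
    right = np.roll(cls, -1, axis=1)
    h_kind = np.zeros((nr, nc), dtype=np.int8)
    h_kind[(left == CYT) & (right == CYT)] = 1
    h_kind[(left == WALL) & (right == WALL)] = 2
    h_kind[(left == CYT) & (right == WALL)] = 3
    h_kind[(left == WALL) & (right == CYT)] = 4

    top = cls[:-1, :]
    bot = cls[1:, :]
    v_kind = np.zeros((nr - 1, nc), dtype=np.int8)
    v_kind[(top == CYT) & (bot == CYT)] = 1
    v_kind[(top == WALL) & (bot == WALL)] = 2
    v_kind[(top == CYT) & (bot == WALL)] = 3
    v_kind[(top == WALL) & (bot == CYT)] = 4

    # membrane interface arrays, facet-resolved
    mem_cyt, mem_wall, mem_cell, mem_facet = [], [], [], []
    mem_horiz, mem_r, mem_c, mem_first = [], [], [], []

    cid_map = layout.cell_id_map

    def emit(horiz: bool, r: int, c: int, cr: int, cc: int, wr: int, wc: int,
             cyt_first: bool, direction: str) -> None:
        cell = layout.cells[cid_map[cr, cc]]
        mem_cyt.append(cr * nc + cc)
        mem_wall.append(wr * nc + wc)
        mem_cell.append(cell.id)
        mem_facet.append(_facet_of(layout, cell, direction, cr, cc))
        mem_horiz.append(horiz)
        mem_r.append(r)
        mem_c.append(c)
        mem_first.append(cyt_first)

    rr, cc_ = np.nonzero(h_kind == 3)
    for r, c in zip(rr.tolist(), cc_.tolist()):
        emit(True, r, c, r, c, r, (c + 1) % nc, True, "right")
    rr, cc_ = np.nonzero(h_kind == 4)
    for r, c in zip(rr.tolist(), cc_.tolist()):
        emit(True, r, c, r, (c + 1) % nc, r, c, False, "left")
    rr, cc_ = np.nonzero(v_kind == 3)
    for r, c in zip(rr.tolist(), cc_.tolist()):
        emit(False, r, c, r, c, r + 1, c, True, "down")
    rr, cc_ = np.nonzero(v_kind == 4)
    for r, c in zip(rr.tolist(), cc_.tolist()):
        emit(False, r, c, r + 1, c, r, c, False, "up")

    return Adjacency(
        h_kind=h_kind,
        v_kind=v_kind,
        mem_cyt_flat=np.asarray(mem_cyt, dtype=np.int64),
        mem_wall_flat=np.asarray(mem_wall, dtype=np.int64),
        mem_cell=np.asarray(mem_cell, dtype=np.int64),
        mem_facet=np.asarray(mem_facet, dtype=np.int8),
        mem_horizontal=np.asarray(mem_horiz, dtype=bool),
        mem_r=np.asarray(mem_r, dtype=np.int64),
        mem_c=np.asarray(mem_c, dtype=np.int64),
        mem_cyt_first=np.asarray(mem_first, dtype=bool),
    )
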