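"""Carrier strengths and physical transport parameters.

Relative carrier strengths are specified per (cell type, transporter,
membrane facet) on a 0-1 scale: 0 means no enhanced permeability at that
facet, 1 the transporter's maximum permeability.  The packaged tables hold
the conceptual scenario library (basic / import-dependent / export-dependent
/ combined / production-decay) and the image-derived detailed models for
developmental stages 15, 16 and 17b.  A missing (cell type, transporter)
row means the transporter is absent from that cell type (strength 0
everywhere).

Effective membrane permeabilities at an interface site combine a
carrier-independent chemiosmotic background with the carrier contributions:

    P_in  = P_bg_in  + P_LAX_max * L(cell type, facet)
    P_out = P_bg_eff + P_PIN_max * (PIN3 + PIN7)(cell type, facet)

with the passive efflux permeability much smaller than the passive influx
(protonated auxin enters membranes readily; the anion barely leaves).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .geometry import CELL_TYPES, FACETS, TissueLayout

EFFLUX_TRANSPORTERS = ("PIN3", "PIN7")
INFLUX_TRANSPORTERS = ("LAX1",)
TRANSPORTERS = EFFLUX_TRANSPORTERS + INFLUX_TRANSPORTERS

CONCEPTUAL_MODELS = ("basic", "import", "export", "combined", "production_decay")
STAGE_MODELS = ("15", "16", "17b")


class ScenarioError(ValueError):
    """Raised for unknown scenarios, transporters or cell types."""


@dataclass(frozen=True)
class Transporter:
    """An auxin carrier and its transport direction."""

    label: str
    mode: str  # "efflux" | "influx"

    def __post_init__(self) -> None:
        if self.label in EFFLUX_TRANSPORTERS and self.mode != "efflux":
            raise ScenarioError(f"{self.label} is an efflux carrier")
        if self.label in INFLUX_TRANSPORTERS and self.mode != "influx":
            raise ScenarioError(f"{self.label} is an influx carrier")


def transporter(label: str) -> Transporter:
    if label in EFFLUX_TRANSPORTERS:
        return Transporter(label, "efflux")
    if label in INFLUX_TRANSPORTERS:
        return Transporter(label, "influx")
    raise ScenarioError(f"unknown transporter {label!r}")


@dataclass(frozen=True)
class FacetStrengthTable:
    """Relative carrier strengths per (cell type, transporter, facet).

    ``entries`` maps ``(cell_type, transporter)`` to an 8-vector in the
    canonical facet order.  Absent pairs mean strength zero.  Entries are
    allowed to exceed 1 after scaling (strength sweeps go beyond the
    default rate); the packaged tables themselves are within [0, 1].
    """

    name: str
    entries: Mapping[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)

    def strengths(self, cell_type: str, transporter_label: str) -> np.ndarray:
        """8-vector of facet strengths (zeros when the carrier is absent)."""
        if cell_type not in CELL_TYPES:
            raise ScenarioError(f"unknown cell type {cell_type!r}")
        if transporter_label not in TRANSPORTERS:
            raise ScenarioError(f"unknown transporter {transporter_label!r}")
        row = self.entries.get((cell_type, transporter_label))
        if row is None:
            return np.zeros(len(FACETS))
        return np.asarray(row, dtype=float)

    def strength(self, cell_type: str, transporter_label: str, facet: str) -> float:
        return float(self.strengths(cell_type, transporter_label)[FACETS.index(facet)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transporter": tr, "cell_type": ct, **dict(zip(FACETS, vals))}
            for (ct, tr), vals in sorted(self.entries.items(), key=lambda kv: kv[0][::-1])
        ]
        return pd.DataFrame(rows, columns=["transporter", "cell_type", *FACETS])

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "FacetStrengthTable":
        entries = {}
        for _, row in frame.iterrows():
            key = (str(row["cell_type"]), str(row["transporter"]))
            entries[key] = tuple(float(row[f]) for f in FACETS)
        return cls(name=name, entries=entries)

    @classmethod
    def from_csv(cls, name: str, text: str) -> "FacetStrengthTable":
        return cls.from_frame(name, pd.read_csv(io.StringIO(text)))


def _load_packaged(fname: str) -> pd.DataFrame:
    with resources.files("fruitflux.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh)


def conceptual_table(name: str) -> FacetStrengthTable:
    """One of the five conceptual scenario tables.

    ``name`` is one of basic, import, export, combined, production_decay.
    """
    if name not in CONCEPTUAL_MODELS:
        raise ScenarioError(
            f"unknown conceptual model {name!r}; expected one of {CONCEPTUAL_MODELS}"
        )
    df = _load_packaged("conceptual_models.csv")
    return FacetStrengthTable.from_frame(name, df[df["model"] == name])


def stage_table(stage: str | int) -> FacetStrengthTable:
    """The image-derived detailed table for a developmental stage.

    Stage 15 has no separation/lignifying rows: its undivided VM file
    carries no enhanced transporters.
    """
    stage = str(stage)
    if stage not in STAGE_MODELS:
        raise ScenarioError(f"unknown stage {stage!r}; expected one of {STAGE_MODELS}")
    df = _load_packaged("stage_models.csv")
    return FacetStrengthTable.from_frame(
        f"stage{stage}", df[df["stage"].astype(str) == stage]
    )


def scale_transporter(
    table: FacetStrengthTable,
    transporter_label: str,
    cell_types: Iterable[str],
    factor: float,
) -> FacetStrengthTable:
    """Scale a carrier's strengths in selected cell types by ``factor``.

    No clipping is applied: sweeps deliberately exceed the default (factor
    1) rate.  Cell types in which the carrier is absent stay absent.
    """
    if factor < 0:
        raise ScenarioError("scale factor must be >= 0")
    if transporter_label not in TRANSPORTERS:
        raise ScenarioError(f"unknown transporter {transporter_label!r}")
    cts = tuple(cell_types)
    for ct in cts:
        if ct not in CELL_TYPES:
            raise ScenarioError(f"unknown cell type {ct!r}")
    entries = dict(table.entries)
    for ct in cts:
        key = (ct, transporter_label)
        if key in entries:
            entries[key] = tuple(v * factor for v in entries[key])
    return replace(table, entries=entries)


@dataclass(frozen=True)
class TransportParameters:
    """Physical transport rates.

    Units: diffusion um^2/s, permeabilities um/s, production/decay in
    arbitrary concentration units ("conc") per second and 1/s.  The apical
    source represents auxin delivered by the style and acts in the topmost
    cell row; production and decay act homogeneously in all cytosol.
    Defaults reflect the chemiosmotic ordering (background efflux much
    smaller than background influx) and the published demonstration values
    for the import-dependent scenario (background influx P_IAAH = 5 um/s,
    full-strength augmented influx P_LAX1 = 100 um/s) are reachable by
    overriding ``P_bg_in`` and sweeping the importer strength.
    """

    D_cyt: float = 600.0
    D_wall: float = 40.0
    P_bg_in: float = 1.0
    P_bg_eff: float = 0.1
    P_PIN_max: float = 5.0
    P_LAX_max: float = 5.0
    production: float = 1e-3
    decay: float = 1e-4
    apical_source: float = 1e-2
    basal_open: bool = True

    def __post_init__(self) -> None:
        for name in (
            "D_cyt", "D_wall", "P_bg_in", "P_bg_eff",
            "P_PIN_max", "P_LAX_max", "production", "decay", "apical_source",
        ):
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be >= 0")
        if self.P_bg_eff >= self.P_bg_in:
            raise ScenarioError(
                "chemiosmotic ordering violated: background efflux permeability "
                "must be below background influx permeability"
            )


@dataclass(frozen=True)
class PermeabilityField:
    """Effective membrane permeabilities per membrane interface site.

    Arrays are aligned with the layout adjacency's membrane interface list:
    ``P_in[k]`` (wall to cytosol) and ``P_out[k]`` (cytosol to wall) in um/s
    for the k-th interface.  Interfaces of ablated cells are absent from
    the list entirely.
    """

    layout: TissueLayout
    P_in: np.ndarray
    P_out: np.ndarray


def assemble_permeabilities(
    layout: TissueLayout,
    table: FacetStrengthTable,
    params: TransportParameters,
) -> PermeabilityField:
    """Combine background and carrier permeabilities on every interface.

    Linear in each of ``P_PIN_max`` and ``P_LAX_max``: carrier strengths
    multiply the transporter-specific maximum permeability.  PIN3 and PIN7
    contributions at the same facet are additive.
    """
    adj = layout.adjacency()

    n_ct = len(CELL_TYPES)
    lax = np.zeros((n_ct, len(FACETS)))
    pin = np.zeros((n_ct, len(FACETS)))
    for i, ct in enumerate(CELL_TYPES):
        for tr in INFLUX_TRANSPORTERS:
            lax[i] += table.strengths(ct, tr)
        for tr in EFFLUX_TRANSPORTERS:
            pin[i] += table.strengths(ct, tr)

    ct_index = {ct: i for i, ct in enumerate(CELL_TYPES)}
    cell_ct = np.asarray([ct_index[c.cell_type] for c in layout.cells], dtype=np.int64)
    ct_of_iface = cell_ct[adj.mem_cell]

    P_in = params.P_bg_in + params.P_LAX_max * lax[ct_of_iface, adj.mem_facet]
    P_out = params.P_bg_eff + params.P_PIN_max * pin[ct_of_iface, adj.mem_facet]
    if np.any(P_in < 0) or np.any(P_out < 0):
        raise ScenarioError("negative effective permeability")
    return PermeabilityField(layout=layout, P_in=P_in, P_out=P_out)
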