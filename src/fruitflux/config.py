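"""Reproducible run configuration and report regeneration.

A :class:`RunConfig` fully determines a simulation: layout, scenario
(carrier-strength table), physical parameters, solver settings and the
requested outputs.  Every run writes a manifest (the config, package
version and solver residual) next to its outputs, and identical configs
produce byte-identical outputs — the model is a deterministic direct
solve with no randomness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .geometry import LayoutSpec, build_layout
from .observables import (
    classify_regime,
    minimum_metrics,
    sweep_strength,
    solve_scenario,
    threshold_strength,
    vm_flux_metrics,
    IndeterminateRegimeError,
)
from .perturbations import (
    AblationSpec,
    CriterionUnreachableError,
    ablation_response,
    production_decay_requirement,
)
from .scenarios import (
    CONCEPTUAL_MODELS,
    STAGE_MODELS,
    FacetStrengthTable,
    TransportParameters,
    conceptual_table,
    stage_table,
)
from .solver import SolverSettings, mass_budget


class ConfigError(ValueError):
    pass


def resolve_table(scenario: str) -> FacetStrengthTable:
    """A strength table from a scenario name or a CSV path.

    Names: the conceptual models (basic, import, export, combined,
    production_decay) or ``stage15`` / ``stage16`` / ``stage17b``.
    """
    if scenario in CONCEPTUAL_MODELS:
        return conceptual_table(scenario)
    if scenario.startswith("stage") and scenario[5:] in STAGE_MODELS:
        return stage_table(scenario[5:])
    p = Path(scenario)
    if p.suffix == ".csv" and p.exists():
        return FacetStrengthTable.from_csv(p.stem, p.read_text())
    raise ConfigError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class RunConfig:
    """A fully serializable simulation request."""

    scenario: str = "stage17b"
    layout: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    outdir: str = "fruitflux_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def layout_spec(self) -> LayoutSpec:
        kwargs = dict(self.layout)
        if "stage" not in kwargs:
            if self.scenario.startswith("stage"):
                kwargs["stage"] = self.scenario[5:]
            else:
                kwargs["stage"] = "17b"
        try:
            return LayoutSpec(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid layout spec: {exc}") from exc

    def transport_params(self) -> TransportParameters:
        try:
            return TransportParameters(**self.params)
        except TypeError as exc:
            raise ConfigError(f"invalid transport parameters: {exc}") from exc

    def solver_settings(self) -> SolverSettings:
        try:
            return SolverSettings(**self.solver)
        except TypeError as exc:
            raise ConfigError(f"invalid solver settings: {exc}") from exc


def run(config: RunConfig) -> dict:
    """Execute one configured simulation and write its outputs.

    Writes the steady concentration field as a delimited-text matrix, the
    summary metrics as JSON, and a manifest.  Returns the manifest dict.
    """
    table = resolve_table(config.scenario)
    layout = build_layout(config.layout_spec())
    params = config.transport_params()
    settings = config.solver_settings()

    conc, flux = solve_scenario(layout, table, params, settings)
    mm = minimum_metrics(conc, layout)
    fm = vm_flux_metrics(flux, layout)
    budget = mass_budget(conc, flux, layout, params)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "concentration.tsv", conc.values, fmt="%.10g", delimiter="\t")
    (outdir / "layout.txt").write_text(layout.to_text())
    (outdir / "cells.json").write_text(layout.registry_json())

    metrics = {
        "ratio_sep_replum": mm.ratio_sep_replum,
        "sep_mean": mm.sep_mean,
        "replum_mean": mm.replum_mean,
        "valve_mean": mm.valve_mean,
        "transversal_vm_flux": fm.transversal,
        "transversal_vm_flux_abs": fm.transversal_abs,
        "parallel_vm_flux": fm.parallel,
        "mass_budget": budget,
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))

    manifest = {
        "package": "fruitflux",
        "version": __version__,
        "config": config.to_dict(),
        "solver_residual": conc.residual,
        "grid": {"nrows": layout.nrows, "ncols": layout.ncols},
        "metrics": metrics,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def regenerate_report(
    outdir: str | Path,
    layout_overrides: dict | None = None,
    sweep_points: int = 9,
) -> dict:
    """Run the full scenario library and write one summary table per result.

    Covers the five conceptual models, the three stage models, the export
    and import strength sweeps with their thresholds and regime classes,
    the four ablation conditions (import/export x partial/full), and the
    production/decay requirement.  Heavier than a single run; the layout
    can be overridden (e.g. fewer rows) to trade resolution for time.
    """
    from .geometry import LIGNIFYING, REPLUM, SEPARATION, VALVE

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lo = layout_overrides or {}
    params = TransportParameters()

    summary: dict = {"scenarios": {}, "sweeps": {}, "ablations": {}}

    # scenario library
    names = list(CONCEPTUAL_MODELS) + [f"stage{s}" for s in STAGE_MODELS]
    if not names:
        raise ConfigError("empty scenario registry")
    rows = []
    for name in names:
        stage = name[5:] if name.startswith("stage") else "17b"
        layout = build_layout(LayoutSpec(**{"stage": stage, **lo}))
        conc, flux = solve_scenario(layout, resolve_table(name), params)
        mm = minimum_metrics(conc, layout)
        fm = vm_flux_metrics(flux, layout)
        rows.append(
            {
                "scenario": name,
                "ratio_sep_replum": mm.ratio_sep_replum,
                "sep_mean": mm.sep_mean,
                "replum_mean": mm.replum_mean,
                "valve_mean": mm.valve_mean,
                "transversal_vm_flux": fm.transversal,
                "parallel_vm_flux": fm.parallel,
            }
        )
        summary["scenarios"][name] = rows[-1]
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "scenarios.csv", index=False)

    # strength sweeps (minimum depth and flux versus carrier strength)
    layout = build_layout(LayoutSpec(**{"stage": "17b", **lo}))
    grids = {
        "export": np.logspace(-2, 0, sweep_points),
        "import": np.logspace(-1, 1.5, sweep_points),
    }
    sweeps = {
        "export": sweep_strength(
            conceptual_table("export"), "PIN3", (SEPARATION, LIGNIFYING),
            grids["export"], layout, params,
        ),
        "import": sweep_strength(
            conceptual_table("import"), "LAX1", (VALVE, REPLUM),
            grids["import"], layout, params,
        ),
    }
    for name, sw in sweeps.items():
        sw.to_frame().to_csv(outdir / f"sweep_{name}.csv", index=False)
        thr = threshold_strength(sw)
        try:
            regime = classify_regime(sw)
        except IndeterminateRegimeError:
            regime = "indeterminate"
        summary["sweeps"][name] = {
            "threshold_strength": thr,
            "regime": regime,
        }

    # ablations: import/export x partial/full
    rows = []
    for scen in ("import", "export"):
        for extent in (0.5, 1.0):
            resp = ablation_response(
                conceptual_table(scen),
                AblationSpec(flanking_replum=0, extent=extent),
                layout,
                params,
            )
            rows.append(
                {
                    "scenario": scen,
                    "extent": extent,
                    "replum_delta": resp.replum_delta,
                    "valve_delta": resp.valve_delta,
                    "noticeable": resp.noticeable(),
                }
            )
            summary["ablations"][f"{scen}_{extent:g}"] = rows[-1]
    pd.DataFrame(rows).to_csv(outdir / "ablations.csv", index=False)

    # production/decay requirement
    try:
        fold = production_decay_requirement(layout, params)
        summary["production_decay_fold"] = fold
    except CriterionUnreachableError as exc:
        summary["production_decay_fold"] = None
        summary["production_decay_deepest_ratio"] = exc.deepest_ratio

    (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
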