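"""Transporter-strength sweeps: thresholds and flux regimes.

Sweeps the apolar VM exporter (export-dependent model) and the
valve/replum importer (import-dependent model, at the published
background influx P_IAAH = 5 um/s), reporting the strength at which a VM
minimum first forms and the flux-based regime classification.
"""

import numpy as np

from fruitflux import (
    LayoutSpec,
    TransportParameters,
    build_layout,
    classify_regime,
    conceptual_table,
    sweep_strength,
    threshold_strength,
)
from fruitflux.geometry import LIGNIFYING, REPLUM, SEPARATION, VALVE

layout = build_layout(LayoutSpec(stage="17b", rows=12, valve_files=4))

export = sweep_strength(
    conceptual_table("export"), "PIN3", (SEPARATION, LIGNIFYING),
    np.logspace(-2, 0, 9), layout, TransportParameters(),
)
thr = threshold_strength(export)
print(f"export model: minimum forms at {100 * thr:.1f}% of the default VM efflux")

# classify the regime over the range where the minimum forms and deepens
formation = sweep_strength(
    conceptual_table("export"), "PIN3", (SEPARATION, LIGNIFYING),
    np.logspace(-2, -0.5, 6), layout, TransportParameters(),
)
print(f"export regime: {classify_regime(formation)} "
      "(transversal VM flux grows as the minimum deepens)")

imports = sweep_strength(
    conceptual_table("import"), "LAX1", (VALVE, REPLUM),
    np.logspace(0, 3, 10), layout, TransportParameters(P_bg_in=5.0),
)
thr = threshold_strength(imports)
print(f"import model: minimum forms at {thr:.1f}-fold over background influx")
print(f"import floor: VM never drops below {imports.ratio.min():.2f} of the replum")
print(f"import regime: {classify_regime(imports)} "
      "(VM through-flux collapses as import strengthens)")
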