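"""The production/decay counterexample.

A classical reaction-diffusion alternative to transporter patterning:
identical basal efflux in all cell types, auxin production confined to
replum and valve, breakdown confined to the VM at ``fold`` times the
baseline decay rate.  The scan shows why this cannot yield a *confined*
minimum: by the time the VM ratio is low, the VM sink has drained the
flanking tissues far beyond any confinement band.
"""

from fruitflux import (
    LayoutSpec,
    TransportParameters,
    build_layout,
    production_decay_metrics,
    production_decay_requirement,
)
from fruitflux.perturbations import CriterionUnreachableError

layout = build_layout(LayoutSpec(stage="17b", rows=12, valve_files=4))
params = TransportParameters()

ref = production_decay_metrics(layout, params, 1.0)
print(f"{'decay fold':>12}{'VM/replum ratio':>18}{'replum vs fold=1':>18}")
for exponent in (0, 2, 3, 4, 6, 8):
    m = production_decay_metrics(layout, params, 10.0**exponent)
    print(f"{10.0**exponent:>12.0e}{m.ratio_sep_replum:>18.4f}"
          f"{m.replum_mean / ref.replum_mean - 1:>+18.1%}")

try:
    fold = production_decay_requirement(layout, params)
    print(f"\nsmallest fold with a deep AND confined minimum: {fold:.3g}")
except CriterionUnreachableError as exc:
    print(
        "\nno decay amplification up to 1e12 produces a minimum that is both\n"
        f"deep (ratio <= 0.5) and confined to the VM: {exc}"
    )
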