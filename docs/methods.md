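# Methods

## Model

The outer epidermis of the fruit is flattened from a cylinder onto a 2D
lattice (grid spacing `h = 2 µm`, one-site walls) that is periodic in the
circumferential direction. Cells are rectangles of cytosol sites separated by
explicit wall (apoplast) sites; treating the wall compartment explicitly is
what gives membrane permeabilities their correct units and lets influx and
efflux contributions be separated quantitatively. Row 0 is apical; the
bottom wall row is held at concentration zero (auxin freely exits toward the
rest of the plant); all other outer boundaries are no-flux.

Tissue ring (circumferential order): valve – VM – replum – VM – valve – VM –
replum – VM. From stage 16 onward each VM strip consists of a lignifying
file (valve-proximal) and a separation file (replum-proximal); at stage 15
the VM is a single undivided file, reflecting that the asymmetric division
creating the two layers has not yet happened.

Dynamics per site (concentration `a`, arbitrary units "conc"):

- cytosol: `da/dt = D_cyt ∆a + p − d·a + s_style·[top cell row] + exchange`
- wall: `da/dt = D_wall ∆a − exchange`

Membrane exchange per unit interface length is `P_in·a_wall − P_out·a_cyt`
into the cell, with

```
P_in  = P_bg,in  + P_LAX,max · L(tissue, facet)
P_out = P_bg,eff + P_PIN,max · (PIN3 + PIN7)(tissue, facet)
```

Carrier strengths are relative values in [0, 1] per (tissue, transporter,
facet) — a fluorescence-derived normalization where 0 means no enhanced
permeability and 1 the transporter's maximum — and multiply a
transporter-specific maximum permeability. PIN3 and PIN7 act additively at a
shared maximum. Each cell's membrane is split into 8 facets (four sides ×
two halves named after the adjacent corner); "inner" is the lateral side
facing the nearest replum midline, assigned mirror-symmetrically, and the
extra site of an odd-length side goes to the inner (resp. upper) half so
facet assignment commutes with mirroring. All packaged table rows that are
left–right symmetric make this convention observably benign.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `D_cyt` | 600 | µm²/s | cytosolic diffusion |
| `D_wall` | 40 | µm²/s | apoplastic diffusion |
| `P_bg_in` | 1 (5 where the import demonstrations fix P_IAAH) | µm/s | background (chemiosmotic) influx |
| `P_bg_eff` | 0.1 | µm/s | background efflux (≪ influx) |
| `P_PIN_max` | 5 | µm/s | efflux permeability at carrier strength 1 |
| `P_LAX_max` | 5 | µm/s | influx permeability at carrier strength 1 |
| `production` | 1e-3 | conc/s | homogeneous biosynthesis, all cytosol |
| `decay` | 1e-4 | 1/s | homogeneous turnover, all cytosol |
| `apical_source` | 1e-2 | conc/s | style-derived input, top cell row |

Geometry defaults: 20 cell rows (a deliberately reduced-height fruit; the
package's standard problem size), 8 valve / 3 replum / 2 VM files per strip
(1 VM file at stage 15); cell widths valve 30, replum 20, VM 10 µm. Cell
height is uniform within a layout — 40 µm at stages 16/17b, 20 µm at
stage 15 — because per-tissue heights cannot share one aligned wall lattice;
the uniform-height choice preserves the relevant biology (narrow VM files;
higher perimeter-to-area ratio of early-stage VM cells, hence more passive
auxin gain per area). All dimensions are configurable.

## Numerics

The steady state solves the assembled sparse linear system directly
(SuperLU); residuals are ~1e-12 relative and recorded in every run manifest.
The explicit forward-Euler mode integrates the identical operator under the
diffusive stability bound `dt ≤ h²/(4·max D)` (further capped by the largest
local rate constant) and is used as an independent cross-check; the test
suite additionally verifies the solver against a naive dense reference
implementation on a ~100-site ring, mass-budget closure (production + apical
input = decay + basal efflux, <1e-6 relative), exact linearity in the
sources, and mirror/periodic symmetry to <1e-10.

Degenerate inputs: a closed tissue with zero decay has no unique steady
state and is rejected; ablated sites are excluded from the operator entirely
(no-flux). Zero-extent ablations are identities. Thresholds from sweeps are
interpolated linearly in log-strength between the bracketing grid points,
since sweeps are log-spaced.

## Observables

Tissue statistics use the middle third of the cell rows, away from apical
and basal boundary effects. The minimum depth is the mean separation-layer
(or undivided VM) cytosolic concentration divided by that of the directly
adjacent ("bordering") replum file, averaged over the four VM strips.
Transversal VM flux is the net horizontal flux through a vertical cut at
each strip midline, summed over the row window; the cut averages the two
membrane interfaces flanking the strip's central wall (the two central
interfaces for an odd-width undivided file), which makes it exactly
mirror-symmetric. Per-strip values are oriented valve→replum and averaged;
a magnitude variant (sum of |flux|) is reported alongside. Parallel flux is
the net basipetal flux through a horizontal mid-window cut across the VM
files.

Regime classification uses the Spearman rank correlation between minimum
ratio and transversal flux magnitude across a sweep: ρ ≤ −0.8 is
flux-passage, ρ ≥ +0.8 flux-barrier, anything weaker is reported as
indeterminate rather than guessed. Net transversal flux saturates once the
minimum is fully formed, so regime classification is most meaningful over
the strength range in which the minimum forms and deepens; the packaged
analyses classify on that range.

## Perturbations

Ablation renders the targeted VM cells totally impermeable — cytosol and,
by default, their bounding wall sites, preventing an apoplastic bypass
through the dead cells' walls (a walls-open variant is available for
sensitivity analysis). Carrier patterns elsewhere are untouched, and no
wound response or repolarization is modeled. Responses are quantified as
relative changes of the directly flanking replum and valve files over the
evaluation window; "noticeable" defaults to a 10% relative change.

The production/decay scan keeps one identical basal efflux pattern in every
cell type, restricts production to replum + valve, and confines decay to VM
cytosol at `fold × d`. The requirement search looks for the smallest fold
giving a deep minimum (ratio ≤ 0.5) that stays confined (valve and replum
means within 25% of their fold-1 values), by coarse log scan plus bisection;
under the default parameters no fold up to 1e12 satisfies both — the VM
sink drains the flanking tissues by 55–80% before or while the depth
criterion is met — so the search reports the criterion unreachable, which is
the quantitative form of "this mechanism is not viable".

## What the defaults do and do not show

The packaged defaults are a self-consistent desk-scale parameterization, not
a fit to measured permeabilities. Conclusions that are robust in this
regime: the basic (basal-PIN-only) pattern yields a VM maximum; apolar VM
efflux yields a minimum at a fraction of the default rate while augmented
import needs several-fold more than its default; the import route has a
depth floor while export deepens essentially without bound; export generates
a flux-passage and import a flux-barrier signature, separated by orders of
magnitude in transversal flux at matched minimum depth; and pure
production/decay cannot make a confined minimum.

Quantities that are sensitive to the unpublished absolute permeability
scales, and where this implementation's numbers should be read as
regime-level rather than exact: the import threshold expressed as a fold
over background sits near 16 here (it is controlled almost entirely by the
background efflux permeability through the VM's passive accumulation ratio
`P_bg,in/P_bg,eff`); the export threshold sits near 29% of default because a
single shared `P_PIN_max` scales both the VM's apolar exporter and the
flanking tissues' basal PIN (whose perimeter-weighted strength is ~1/3), so
the crossing is pinned near that ratio; the import floor is ~0.2 rather
than ~0.5 for the same passive-accumulation reason. Similarly, because every
cell produces auxin and a carrier-less file sheds its content mostly
sideways (the lateral/vertical leak ratio of a file is set by geometry,
roughly perimeter/width ≈ 10), removing the VM deprives the flanking files
of a noticeable supply in *both* scenarios, which masks part of the
ablation-based regime discrimination at this scale: the flanking replum
drop is reproduced, the flanking valve rise and the import model's
near-invariance are not.

## Limitations

2D lattice (no curved geometry, no internal septum or third dimension); no
growth or division; transporter patterns are static inputs — their dynamic
(re)polarization is out of scope; linear carriers (no saturation, pH
dependence, or ABCB transporters); concentrations are in arbitrary units, so
only ratios, folds and thresholds are meaningful outputs.
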