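# Methods

`epistrat` simulates the self-organization of a stratified epidermis — basal,
spinous and granular layers emerging from a single basal monolayer — with a
three-scale model: an off-lattice subcellular-element representation of cell
mechanics, a four-stage stochastic cell lineage, and a continuum calcium
field coupling the two.

## The lineage model

Four compartments: basal stem cells (`c0`), proliferative spinous (`c1`),
mature spinous (`c2`), granular (`c3`), with dynamics

    dc0/dt = (2 p0 - 1) v0 c0
    dc1/dt = 2 (1 - p0) v0 c0 + (2 p1 - 1) v1 c1
    dc2/dt = 2 (1 - p1) v1 c1 - d2 c2
    dc3/dt = d2 c2 - d3 c3

`p0`, `p1` are the probabilities of self-renewal at division, `v0 = ln2 /
(cycle length)` and `v1` the division rates, `d2` the spinous-to-granular
maturation rate, `d3` the granular removal rate.  The stem pool is maintained
iff `p0 > 1/2`; `critical_self_renewal()` returns this threshold.

The Ovol1/Ovol2 transcription factors (effective levels α, β per genotype)
repress proliferation and self-renewal and promote terminal differentiation:

    v0 = vmin + vT / (1 + ω α + χ β)
    p0 = pmin + pT / (1 + λ α + μ β)
    d2 = dDKO + ς α + ξ β

Genotype presets (WT α=β=1; Ovol1-null α=0, β=1.25; Ovol2 skin knockout
α=1.6, β=0; Ovol2 overexpressor α=0.5, β=10; double knockout α=β=0) encode
the mutual Ovol1–Ovol2 repression as fixed levels.

### Default rates and how they were chosen

The defaults are a calibrated set, constrained simultaneously by:

1. every direction call of the mutant phenotype table (5 genotypes × 3
   layers, threshold θ=20% relative change at a 10-day horizon) must be
   reproduced with margin;
2. wild type must sit clearly above the maintenance threshold
   (default p0 = 0.545, so the tissue visibly grows over five days);
3. the calcium feedback must be able to push the effective p0 below 1/2
   (hence pmin = 0.45 < 1/2), otherwise no homeostatic steady state exists.

Constraint 1 pulls the genotype-to-genotype spread of p0 toward zero while
constraint 3 demands strong β-sensitivity; these are reconciled by a small
regulatory weight μ (so the overexpressor's β=10 barely moves p0) combined
with a large feedback gain on β (see below).  The frozen values live in
`OvolRegulation` and are configuration, not constants.

## Cell mechanics

Each cell is a cluster of point elements.  Same-cell elements interact
through an all-pairs harmonic spring `V = μ (r - r0)^2 / 2`; elements of
different cells through a truncated Lennard-Jones potential
`V = F ε ((σ/r)^12 - (σ/r)^6)` with `F = Fa` for same-class and `F = Fb` for
cross-class pairs (classes: basal / spinous / granular — the two spinous
stages share a class).  Motion is overdamped with additive Gaussian noise.
Membrane-adherent elements of basal cells feel a constant-magnitude pull
`V = ε_ext |z|` toward the basement membrane within one membrane cutoff; a
stiff numerical wall below z = 0 keeps the membrane impenetrable.

Numerical choices worth knowing:

* **Element count and size.** All-pairs equal-rest springs relax the
  elements of a cell onto a thin spherical shell.  Many small elements make
  hollow shells that interpenetrate under load — the tissue then compresses
  to about half its cell volume and all vertical ordering is lost.  The
  default is therefore six large elements (σ = 4.5 µm, r0 = 2 µm): the
  shell gaps stay below the repulsion range and cells behave as solid soft
  spheres with a packed diameter of ≈ 4.75 µm.
* **Displacement cap.** Freshly divided cells overlap their neighbours and
  produce near-singular repulsion.  Each element's per-step displacement is
  individually capped at 0.15 σ (kept below half the neighbour-list skin);
  capped elements are counted.  A global step-rejection rule was tried and
  rejected: one overlapping pair then freezes the whole tissue every step.
* **Substepping.** Mechanics runs 40 relaxation substeps of 36 s per
  simulated hour — a quasi-static treatment (the relevant comparison is the
  relaxation time against the 24 h cycle, not wall-clock coverage).  The
  stability bound `mobility · dt < 2 / k` for the stiffest pair mode caps dt.
* Forces are evaluated over a Verlet candidate list built by cell-linked
  binning; identical seeds give bit-identical trajectories.

## Lifecycle

Cells grow by scheduled element addition (birth size half the target,
reaching the target over one cycle), divide when their jittered cycle clock
expires at full size, and follow the lineage stage machine C0→C1→C2→C3.

* Symmetric divisions use a plane roughly perpendicular to the membrane
  (±15° jitter): daughters side by side.  Asymmetric basal divisions
  (asym_division variant and up) use a plane roughly parallel to the
  membrane: one basal daughter keeps the membrane contact, the suprabasal
  daughter becomes C1.  The probability weights (asymmetric `2(1-p0)`,
  symmetric renewal `2p0-1`, generalized below p0 = 1/2) preserve the
  population model's expected offspring composition.
* Daughters are pushed 2 µm apart along the division axis (anaphase
  separation; upward-only for asymmetric divisions) so they resolve into
  distinct bodies within a few steps.
* **C2→C3 timing.** The default is a fixed maturation age `1/d2_eff`
  (mean residence identical to the rate model).  The memoryless per-step
  hazard `1 - exp(-d2_eff dt)` is available as `maturation = "hazard"`.
  The choice matters: with CV = 1 timing noise the granular band loses
  coherence even in a perfectly age-ordered tissue; with fixed age the
  conveyor ordering of the tissue maps age onto height and the
  spinous–granular boundary stays sharp.  Aggregate per-capita rates match
  the ODE coefficients under both modes.
* Expired granular cells shrink by one element per tick over 4 h, then
  disappear.

## Variants

Each variant adds one mechanism (config-level ablation recovers the
previous one exactly):

* `base` — symmetric divisions only, isotropic adhesion (Fa = Fb), and
  *unpolarized* substrate adhesion: any element near the membrane sticks to
  it.  Nothing aligns the layers; the tissue stays stochastically mixed.
* `asym_division` — adds oriented asymmetric basal division together with
  polarized adhesion (substrate pull restricted to the membrane-adherent
  elements of basal cells).  These two are introduced together deliberately:
  they are two faces of the same cell-polarity mechanism, and separating
  them leaves the base model with an ordering mechanism it should not have.
* `selective_adhesion` — adds Fa > Fb (defaults 2.0 / 0.5, ratio 4).
* `signal` — adds the calcium feedback.

## Calcium field and feedback

The field `s` lives on a regular grid (default 3 µm voxels) and obeys
`∂s/∂t = ∇·(D ∇s) + δ1 c2 + δ2 c3 - ds s` with conservative flux-form
central differences and forward-Euler substeps.  Per-voxel diffusivity is
the baseline divided by the local element count (floored at one), averaged
with the six face neighbours: crowded tissue slows transport.  Secretion is
deposited per element so per-cell totals are exact; granular cells secrete
twice the spinous rate.  Cells read the field back as the mean over their
elements' voxels.

The relaxation block (1000 substeps, dt at 80% of the stability bound
`h²/(6 D)`) runs once per lifecycle step and reaches the quasi-steady field
for the current sources — chosen deliberately: with a much smaller substep
the field lags the tissue by half a day and the feedback loop oscillates.

Feedback (Signal variant only, sampled at decision time): local calcium
raises the effective Ovol1 level inside mature spinous cells,
`α_eff = α (1 + k_α s/(s_half+s))` (faster maturation), and the effective
Ovol2 level inside basal cells, `β_eff = β (1 + k_β s/(s_half+s))` (lower
v0 and p0).  The fixed point where `p0_eff = 1/2` sets the homeostatic
tissue size; `s_half = 0.18` places that plateau near the five-day size of
the unregulated variants, and `k_β = 600` compensates the small μ (see the
lineage calibration note above).

## Stratification metrics

A tissue is cut into horizontal slices of 0.75 cell diameters (the cells
are oblate, so "one cell size" along z is thinner than the packing
diameter).  Each slice becomes a 10×10 label image (0 basal, 1 spinous, 2
granular; modal label per pixel, ties to the lowest, empty pixels filled
from the nearest occupied pixel but masked).  The Sharpness Index is one
minus the mean squared central difference over occupied interior pixels;
it is 1 for a uniform slice and bounded below by −3.  Note the stride-2
central difference is blind to period-2 alternation — a checkerboard also
scores 1; the metric is meant for comparing similar images, not as an
absolute sharpness measure.  The Isolation Ratio of a class is the fraction
of its cells outside the largest connected cluster (centroids linked within
1.2 cell diameters; ties broken toward the expected layer height).
Per-slice Ripley's K uses the periodic minimum image, so no edge correction
is applied.

Pattern classification for parameter sweeps follows rule-based thresholds
(dominant-class purity ≥ 0.7 in ≥ 70% of slices, per-type isolation ≤ 0.1,
no internal cavities).  A known limitation: with the desk-scale granular
turnover (~12 h residence) the granular layer is a single sparse cell sheet
whose largest connected cluster rarely exceeds half the class even in
visually layered tissues, so the isolation clause keeps interior sweep
values from classifying as stratified; the purity and sharpness clauses are
the discriminating ones at this scale.

## What the synthetic conditions do and do not show

All experiments start from a synthetic basal monolayer (7×7 to 10×10 cells,
periodic in x–y) and run for five simulated days — the embryonic
stratification window.  This emulates layer *formation*, not adult
homeostasis: there is no cornified layer, no periderm, no deformable
membrane, and the domain is far smaller than real epidermis, so absolute
cell counts and the steady-state magnitudes of mutant phenotypes are out of
scope; direction calls, metric orderings across variants, and the
feedback's size control are what the tests pin down.  Passing tests on
these synthetic tissues demonstrates internal consistency of the mechanisms
at desk scale, not quantitative agreement with mouse epidermis.

## Problem sizes

Unit tests use 1–16 cells.  The acceptance-style tests run 7×7 monolayers
for 120 h (≈ 400–700 cells, ≈ 2500–4000 elements); the reproduction script
runs 10×10 monolayers for 120 h, five seeds per variant.  Ten-day runs are
used only for the homeostasis check.
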