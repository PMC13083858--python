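# Methods

## Geometry: the synthetic root-tip template

The template is a rectilinear idealization of an *Arabidopsis* root tip:
axis-aligned rectangular cells of unit depth (1 µm) on a grid, with the root
axis vertical and the tip at the minimal axial coordinate. From the tip
upward: `columella_tiers` tiers of `columella_width` columella cells, a
single quiescent-centre (QC) cell on the axis, and two mirror-symmetric
flanks of tissue files (stele, endodermis, cortex, epidermis from the axis
outward; `n_files_per_flank` ≤ 4 keeps the outermost types). Lateral
root cap (LRC) layers hug the outermost file over the root-cap and meristem
rows. Rows are assigned to zones (root cap / meristem / transition /
elongation) by the `zone_boundaries` row indices.

Default dimensions are order-of-magnitude *Arabidopsis* values, all
config-exposed: cell width 20 µm; cell heights 15 µm (root cap, meristem),
30 µm (transition), 60 µm (elongation); wall thickness 0.2 µm; 3 columella
tiers × 3 cells; 2 LRC layers; 10 rows per flank file with zone boundaries
(2, 6, 8). This yields 114 cells and 258 wall segments (372 state
variables). The template is explicitly *not* a replica of any imaged root:
real templates are extracted from confocal sections with curved outlines
and unequal cell counts. What the idealization preserves — and all the
transport model consumes — is volumes, membrane contact areas, adjacency,
zone/type labels and left/right symmetry.

Walls are per-segment compartments: every maximal shared edge between two
cells is one interior wall (volume = contact area × wall thickness); edge
pieces not shared with a neighbour become exterior walls. Each (cell, wall)
incidence carries one membrane. Adjacent wall segments meeting at a grid
junction are diffusively coupled (see below), so the apoplast forms a
connected network even across geometric notches (e.g. around the QC).

Gravity is carried by labels, not rotation: after the 90° reorientation the
flank at x < 0 is called *lower* and x > 0 *upper*. Lateral membranes are
labelled by absolute lateral direction (`toward_lower_flank` /
`toward_upper_flank`) rather than relative to the axis, because the
gravistimulus rule ("move columella PIN3/PIN4 to the lower side of each
cell") needs an absolute direction on every columella cell, including the
off-axis ones. Transverse membranes are `rootward` / `shootward`.

The `mirror` map is a geometric involution (x → −x) over all cell, wall and
membrane ids, fixing on-axis entities. It is used both as a validity
invariant (type, zone, volume, area must be mirror-equal) and as the
machine-precision symmetry oracle for the transport model: a symmetric
system must produce a symmetric steady state and a lower/upper ratio of
exactly 1 without a stimulus.

## Carrier placement

Densities are dimensionless multipliers of the carrier permeabilities.
Defaults follow the standard published root-tip distributions: AUX1 on all
membranes of LRC, epidermis and columella cells; PIN1 rootward in the
stele; PIN2 shootward in epidermis and LRC; PIN3/PIN4/PIN7 apolar in the
columella before the stimulus. Plasmodesmatal density is uniform (1) on
interior walls. All placements are overridable in the `carriers:` config
block.

Gravistimulus rule: for each columella cell and each of PIN3 and PIN4, the
summed density over the cell's membranes is conserved and redistributed
onto the membranes facing the lower flank (ties split proportionally to
membrane area). Conservation ("repositioned" = moved, not created) is a
modelling choice; setting the lower density to a fixed value instead would
make the perturbation magnitude depend on membrane count. PIN7 is left in
place by default (`relocate_pin7` switches it on), since only PIN3 and PIN4
are described as relocating.

AUX1 scenarios (`basal`, `global_scale`, `lower_scale`, `upper_scale`,
factor F > 0, default 10) multiply AUX1 densities on the selected membrane
set; on-axis cells are untouched by the one-sided modes. Scenario scaling
and the gravistimulus commute (disjoint density sets), and both are applied
at t = 0, simultaneously with each other.

## Transport model

One linear ODE per compartment, `dc/dt = M c + s` (see README for the
term-by-term flux contract). Units: permeabilities µm/s, wall diffusivity
µm²/s, volumes µm³; concentrations are dimensionless — the model is linear,
so the absolute scale cancels in every reported ratio. The flank-averaged
epidermal series can optionally be normalized by their joint pre-stimulus
value so basal curves start near 1.

pH partitioning of auxin (protonated fraction crossing passively, anionic
fraction requiring carriers) is folded into the effective permeabilities
`P_in_bg`/`P_out_bg`/`P_aux1`/`P_pin`; this keeps the system linear and
needs no dissociation constants. Default parameters (config-exposed,
chosen once as literature-order-of-magnitude values for this model family):

| parameter | default | meaning |
|---|---|---|
| `P_in_bg`  | 0.3 µm/s | passive background influx |
| `P_out_bg` | 0.3 µm/s | passive background efflux |
| `P_aux1`   | 0.5 µm/s | influx per unit AUX1 density |
| `P_pin`    | 1.0 µm/s | efflux per unit PIN density |
| `D_wall`   | 30 µm²/s | apoplastic diffusion coefficient |
| `P_pd`     | 0.5 µm/s | plasmodesmatal permeability per unit density |
| `alpha`    | 10⁻³ /s (QC, columella), 10⁻⁴ /s elsewhere | synthesis |
| `delta`    | 5×10⁻⁴ /s | degradation (cells only) |
| exterior   | closed | optional fixed-concentration bath (`c_ext`, `P_ext`) |

Wall-to-wall coupling: two wall segments sharing a junction point exchange
at rate `D_wall · a/ℓ`, with cross-section `a` = wall thickness × depth and
`ℓ` the distance between segment centroids. This is a lumped finite-volume
approximation of apoplastic diffusion; it under-resolves gradients along
long walls but preserves connectivity and mass exactly.

Assembly adds every exchange as a matched (+into receiver, −out of donor)
amount pair, so `M` is Metzler by construction and, for a closed system
without turnover, the volume-weighted column sums of `M` vanish
identically — mass conservation is a structural property, not an integrator
accuracy claim (BDF then preserves this linear invariant to solver
precision; observed drift ~10⁻¹³ relative over an hour).

Steady states are computed by sparse LU (`splu`); singular systems (closed,
δ = 0, nonzero synthesis) are detected via the post-solve residual and
reported as having no steady state. Transients use `solve_ivp` BDF with
rtol 10⁻⁸, atol 10⁻¹², constant sparse Jacobian. Tiny negative undershoots
(≲10⁻⁶ of scale) are clipped to 0; larger negativity is an error. The model
is fully deterministic; no seeds are involved.

## Gravitropic experiments

Protocol: assemble the symmetric system, solve for its steady state, apply
gravistimulus + scenario, integrate from that state over the sample grid
(default: every 30 s to 10 min, then every 5 min to 6 h, matching a 6-h
gravistimulation time course). The asymmetry statistic averages the
transition-zone epidermal cells per flank (2 per flank in the default
template).

"Establishment of asymmetry" is operationalized as the lower/upper ratio
first reaching a threshold, default 1.2, linearly interpolated between
samples. When the threshold is never reached within the horizon the
crossing time is `None`, compared as "slower than any finite time": under
the default parameters the basal ratio saturates near 1.004, so the
lower×10 scenario (crossing ≈ 441 s) is faster by that convention, and the
ratio-curve comparison (global×10 deviates from basal by ≈ 0.003 at most,
lower×10 by ≈ 0.22) carries the quantitative content of the "limited
effect" vs "faster establishment" contrast.

The long-time equivalence check integrates from the zero field to
3×10⁴ s: the slowest system mode is ≈ δ = 5×10⁻⁴ s⁻¹, so 15 relaxation
times suffice for < 10⁻⁵ relative agreement with the direct solve.

## Quantification procedures

* **Angle sectors.** Angles reduced modulo 360° into half-open sectors
  [k·w, (k+1)·w); w must divide 360 (20° → 18 sectors, 30° → 12). Reported
  as counts and percentages of seedlings. The sign/reference convention of
  the input angles (deviation from the initial vertical) is the caller's.
  A wrapped-normal sampler provides synthetic bending-angle samples.
* **Relative import.** (x₁₅ − x₀)/x₀ × 100 on protoplast-associated
  radioactivity counts. The source description of this quantity mixes
  "supernatant" and "protoplast" wording with ambiguous precedence; the
  implemented reading is the percent change of protoplast counts, the only
  one consistent with "relative import into protoplasts" (it is 0% when
  nothing is imported and 50% for 150 vs 100 counts). The supernatant
  reading remains computable by passing those counts instead.
* **Band quantity.** Background-adjusted volume over background-adjusted
  reference volume; the reference band is 1.00 by construction; invariant
  under common rescaling.

## Trajectory metrics

RMSD uses the Kabsch SVD solver (proper rotations only; collinear inputs
are rejected as ill-conditioned). An independent quaternion
characteristic-polynomial solver is kept as a cross-check — the two agree
to < 10⁻⁸ on random instances, and against MDAnalysis in the test suite.
RMSF superposes all frames onto an iteratively refined mean structure
(2 iterations, as is conventional; the choice matters little for the
synthetic fixtures) and reports per-residue √⟨‖r − r̄‖²⟩. For isotropic
per-axis jitter σ the expected RMSF is σ√3; superposition removes six
rigid-body degrees of freedom, biasing the estimate low by roughly
√(1 − 6/(3N)), i.e. ~1% at N = 100 residues — within the 2% recovery
check. Replica averaging over independent runs is provided
(`average_rmsf`) but not applied silently.

The synthetic generator places residues on an ideal α-helical backbone
(2.3 Å radius, 100°/residue, 1.5 Å rise) and adds i.i.d. Gaussian
displacements per frame. It emulates only the stationary fluctuation
amplitude profile of a Cα trajectory — no correlated motions, no slow
conformational drift, no solvent or membrane context — so recovery tests
validate the metric implementations, not any claim about real MD output.

## Known limitations

* Rectilinear geometry; no growth, division, or curved outlines. Absolute
  concentration patterns therefore differ from image-derived templates;
  conclusions should rest on symmetric-vs-perturbed comparisons, which the
  symmetry machinery makes exact.
* Linear carrier kinetics: no saturation, no auxin-dependent carrier
  trafficking.
* The asymmetry threshold (1.2) and the default parameter set are
  conventions; both are config-exposed and all qualitative orderings
  reported by the scenario comparison are stable under the defaults.
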