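# Methods

## Scope and approach

The package re-creates, on synthetic geometry, the computational experiment
of enhancing Tumor Treating Fields (TTFields) exposure by virtual skull
surgery. Patient MRI head models are replaced by a parametric five-layer
sphere phantom; every surgical manipulation is a pure *relabeling* of mesh
elements, so paired scenarios (with/without craniectomy, with/without
resection) share one discretization and support exact element-by-element
difference maps, paired medians and coefficients of determination without
interpolation.

Conclusions drawn here are phantom-scale analogues of the clinical
modeling findings — directions and shapes of effects, not patient-specific
field values, which would require individual anatomy.

## Head phantom

Concentric spheres with default outer radii (mm):

| layer | outer radius | thickness |
|---|---|---|
| scalp | 92 | 7 |
| skull | 85 | 6 |
| CSF | 79 | 3 |
| gray matter | 76 | 16 |
| white matter | 60 | — |

The tumor is an axis-aligned ellipsoid. The default *superficial*
configuration uses semiaxes 25 × 17.5 × 25.5 mm (a 50 × 35 × 51 mm lesion,
volume 46.7 cm³) centred at (31, 0, 0) mm, placing the tumor surface 20 mm
below the cortical (GM) boundary along +x. The *deep* variant (16 × 25.5 ×
20.5 mm semiaxes) sits at the head centre, emulating a thalamic lesion.

### Meshing

The mesh is an "onion" of concentric geodesic (subdivided-icosahedron)
shells joined by triangular prisms, each split into three tetrahedra with
the smallest-global-index diagonal rule, which triangulates shared quad
faces identically in adjacent prisms — the mesh is conforming by
construction. A tet fan connects the innermost shell to the centre node.
Shell radii include every layer boundary exactly, so compartment volumes
converge to the analytic shell volumes (0.1–1% at default resolution);
tumor membership is decided per element by its centroid falling inside the
ellipsoid (volume error < 1% at default resolution, < 5% across tested
resolutions). The default `target_edge_length` of 6 mm selects icosphere
level 4 (2562 vertices per shell) and yields ≈220k tets / 38k nodes —
small enough for interactive scenario sweeps, fine enough to resolve 15-mm
burr holes with ~13 surface triangles each.

### Virtual surgery

* **Craniectomy** — skull elements whose centroids fall inside a
  cylindrical footprint along the defect's centre direction are relabeled
  as scalp ("replacing the bone flap with skin"). Shapes: circle (10–100
  mm), oval flap (e.g. 50 × 67 mm), and multi-cylinder burr-hole patterns.
  The default four-hole pattern places 15-mm holes at ± half the tumor's
  projected semiaxes in the tangent plane — the centres of an even 2 × 2
  partition of the projection — for a total area of 707 mm², identical to
  one 30-mm disc.
* **Resection** — every tumor element is relabeled CSF (cavity filled with
  CSF, the state representative of most exposure time after surgery).
* **Peritumoral shell** — non-tumor brain elements with centroids strictly
  closer than 10 mm (configurable) to the triangulated tumor boundary,
  computed with a KD-tree-prefiltered exact point-triangle distance. Flags
  are set against the pre-resection boundary and survive resection.

The defect footprint area is measured volumetrically (relabeled volume /
skull thickness); summing relabeled boundary-face areas carries a ≈ +5%
systematic bias (tet centroids sit deeper than their outer faces) plus
triangle granularity and was rejected.

## Synthetic diffusion tensors

Each GM/WM/tumor element receives an axially symmetric tensor with
tissue-wise mean diffusivity and fractional anisotropy, principal axis
radial in WM (fibres crossing the layered geometry) and tangential in GM:

| tissue | MD (10⁻³ mm²/s) | FA | orientation |
|---|---|---|---|
| GM | 0.89 | 0.15 | tangential |
| WM | 0.69 | 0.70 | radial |
| tumor | 0.95 | 0.10 | radial |

For target FA and MD m, eigenvalues are λ₁ = m(1+2δ), λ₂ = λ₃ = m(1−δ)
with δ = FA/√(3 − 2 FA²). Each element's tensor is scaled by a log-normal
factor exp(N(0, σ)) with σ = 0.25, sized so mapped-conductivity IQRs land
on the few-×10⁻² S/m scale reported for patient data; scaling the whole
tensor preserves FA exactly. All randomness flows through one
`numpy.random.default_rng(seed)`.

What the generator does *not* emulate: cortical folding, true fibre
tracts, oedema gradients, susceptibility artefacts. Passing tests
therefore demonstrate the pipeline's correctness and the *physics* of
defect-mediated field enhancement, not patient-level prediction accuracy.

## Conductivity mapping

CSF / scalp / skull are isotropic at 1.654 / 0.465 / 0.010 S/m. Brain and
tumor tensors are mapped directly, σ = s·D. The slope minimizes the MSE of
the mean-eigenvalue (trace/3) scalar conductivities of *healthy* GM/WM
(tumor and peritumoral shell excluded) against 0.275 and 0.126 S/m; with
the linear trace/3 summary the optimum is closed form,

    s* = (0.275 Σ_gm m_i + 0.126 Σ_wm m_i) / Σ_gm∪wm m_i²,

verified against a bounded 1-D search. trace/3 was chosen over the
geometric mean precisely because it is linear in s. Tumor tensors are
mapped with the same slope but excluded from the fit. With default
parameters and seed 1 this gives s* ≈ 205 and mapped medians ≈ 0.18 (GM),
0.14 (WM), 0.19 (tumor) S/m — inside the 0.10–0.43 S/m range measured for
gliomas in vivo. SAR densities: scalp 1109, skull 1908, CSF 1007, brain
and tumor 1045 kg/m³ (config-overridable).

## Field solver

P1 tetrahedral FEM for ∇·(σ∇φ) = 0; element matrices V·GᵀσG with exact
constant gradients. Electrodes are uniform-current-density Neumann patches
(one per array; geodesic rectangles of 70 × 50 mm by default, or spherical
caps for validation) with loads integrating exactly to ±I; I = 0.9 A per
pair, the peak of the 1.8 A peak-to-peak waveform (exposed as config,
since a peak-vs-peak-to-peak reading is a genuine ambiguity). One static
solve per pair represents the duty-cycle maximum; fields scale linearly
with current at other phases.

The pure-Neumann nullspace is removed by grounding one node and
re-centring the solution to zero mean (identical to a zero-mean
constraint, but it keeps the reduced operator sparse and SPD); the linear
solve is Jacobi-preconditioned CG to a verified relative residual ≤ 1e-9
of the full singular system, typically ~350 iterations and < 1 s at
default resolution. Linearity and reciprocity hold bitwise because the CG
iteration is exactly homogeneous under sign flips and powers of two.

Degenerate elements (volume ≤ 1e-9 of the maximum) abort assembly with the
offending ids.

### Validation oracles

* **Slab**: full opposite faces of a 100-mm cube at σ = 0.5 S/m and 0.9 A
  give |E| = I/(Aσ) = 180 V/m; the discrete solution reproduces the exact
  linear potential to solver precision, and the raw flux audit closes to
  1e-12.
* **Layered sphere**: per harmonic degree n the radial profile is
  A rⁿ + B r^−(n+1); interfaces are traversed with the bounded reflection
  variable t = (B/A) r^−(2n+1) (admittance recursion), stable to arbitrary
  n unlike the naive interface matrix. Electrodes are point sources or
  uniform-current caps (closed-form Legendre coefficients). The surface
  series is conditionally convergent, so partial sums are window-averaged
  (Cesàro-style, window ≤ 512 terms) and convergence is declared when
  consecutive window means differ < 1e-8 in relative L2; a too-short
  expansion raises instead of returning a truncation artefact. The
  homogeneous-sphere reduction matches the textbook two-point-source
  closed form (via a 2° cap) to 0.1%; a 4-layer head-like sphere at
  default resolution agrees with the FEM surface potential to 0.9%
  relative L2 (acceptance bound 2%). Interior evaluation (stable layer-wise
  back-substitution) confirms the insulating-skull limit: interior
  potential → 0.
* **Flux audit**: raw per-element J·n integration. On the slab all
  quantities close below 0.1%; on curved geometry the per-patch raw
  mismatch is first-order-inaccurate (the scalp is one element thick) and
  is reported, while the conservation balance (inflow = outflow) closes to
  ~1e-5 and is the asserted quantity. Residual-based audits are
  tautological for a pure-Neumann solve and are deliberately not used.

## Efficacy metrics

TER is a cubic in |E| (descending coefficients 4.06e-7, −1.72e-4, 2.96e-2,
−1.54) on 110–240 V/m, zero below, 1.245 above. The published
3-significant-digit coefficients evaluate to 1.269 at 240 V/m — above the
published end-of-range value — so the cubic is additionally capped at the
clamp inside the interval, which restores monotonicity; below ≈238.6 V/m
the mapping is the unmodified cubic (TER(110) ≈ 0.175, TER(225) ≈ 1.04,
the growth-arrest point).

All region statistics are element-volume weighted ("percentage of tissue"
= volume fraction): quantiles interpolate linearly between order
statistics at cumulative-weight midpoints (reducing to the unweighted
sample median for equal volumes); P100/P225 count volume with |E| ≥ 100 /
≥ 225 V/m (inclusive; ties are measure zero); SAR = (E·σE)/ρ per element,
with medians and 99th percentiles reported for the skin under the
electrode arrays and over the defect. Paired statistics (Δ|E|, fraction
increased, volume-weighted Pearson r²) require identical geometry hashes.

## Experiments and problem sizes

`PhantomStudy` builds mesh, tensors, slope and electrodes once; scenarios
are relabelings solved from scratch (no warm starts), making every row of
a sweep independently reproducible; identical config + seed gives
byte-identical CSV reports. Default experiment sizes: ≈220k tets per solve,
two pairs per scenario, 20 scenarios for the 10–100 mm diameter sweep —
about a minute end to end.

Representative seed-1 results: a 50-mm craniectomy raises the superficial
tumor's median |E| for the overlying L/R pair from 121.5 to 194.9 V/m
(+60%), P225 from 0.3% to 11.4%, with contralateral healthy medians moving
< 5%; the sweep peaks near 55–60 mm and declines < 5% thereafter; four
burr holes ≥ the equal-area 30-mm circle on both pairs; post-resection
peritumoral enhancement persists (+64%); the central deep tumor changes
< 1% for the pair remote from the defect.

## Design choices on genuinely open points

* **A/P pair geometry.** Arrays are placed on the ±y axis, orthogonal to
  the defect. On the idealized sphere only the overlying pair benefits
  from the corridor; clinically planned (tumor-centric) layouts would tilt
  both pairs toward the lesion. We kept the symmetric layout and state
  per-pair results rather than tuning patch positions.
* **Electrode model.** One contiguous rectangular patch per array (no 3×3
  transducer discs, no contact impedance): at matched total current the
  deep field distribution is insensitive to intra-array structure.
* **Current amplitude.** 0.9 A (waveform peak) per active pair,
  config-overridable.

## Limitations

Spherical anatomy (no gyrification, no skull-thickness variation); static
real-valued conductivities (no dielectric dispersion or capacitive
currents); no thermal model beyond the SAR statistic; no electrode-layout
optimization; patient-specific field values are out of reach by design.
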