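# Methods

## The model

`lesionlab` studies how macroscopic cracks produced by intravascular
lithotripsy (IVL) in a calcified coronary plaque affect stent-expansion
outcomes. The artery is idealized as a straight, concentric, two-layer
tube: a media+intima layer (0.32 mm) and an adventitia (0.34 mm) around a
3 mm-diameter healthy lumen, 40 mm long. A 10 mm lesion centered on the
axis carries a 70 % area stenosis (stenotic lumen radius
r√(1−0.70) ≈ 0.822 mm) and a calcified arc of constant thickness
t = 1.1 mm spanning θ_c ∈ {90°, 270°} — a localized versus a distributed
plaque. Soft (lipidic) plaque fills the remaining plaque annulus.

A lithotripsy-induced defect is a volume removed from the calcium,
parametrized nondimensionally:

- width w = θ(w̃)/θ_c, where θ(w̃) = arccos(1 − w̃²/2r_c²) is the central
  angle subtended at the calcium mid-surface radius r_c by a chord of
  length w̃ (identically 2·arcsin(w̃/2r_c));
- length l = l̃/L_c, the defect's axial extent over the lesion length.

Three morphologies are modeled: **sided** (flush with one circumferential
edge of the arc), **centered** (bisecting the arc), and **through**
(bisecting the arc with l = 1, splitting the calcium into two fragments).
The factorial design crosses the two arc angles with one intact baseline,
sided and centered defects at (l, w) ∈ {1/3, 2/3}², and through defects at
w ∈ {1/3, 2/3} — 11 models per arc, 22 in total.

## Geometry construction

Cross-sections are exact labeled partitions into annular sectors, so areas
(stenosis, ring conservation) are closed-form rather than mesh-dependent.
Two geometric choices deserve note:

- **Radial placement of the calcium.** A 1.1 mm-thick calcium ring cannot
  fit between the stenotic lumen (0.822 mm) and the healthy wall (1.5 mm).
  The calcium inner face is placed at the stenotic lumen radius plus a
  0.1 mm soft rim, and the media/adventitia are displaced outward over the
  arc (outward remodeling, as severely calcified vessels exhibit); r_c is
  the calcium mid-surface radius (≈1.47 mm with defaults). The
  ring-conservation check therefore compares the label areas against the
  actual (locally bulged) outer boundary.
- **Carve shape.** The default carve is an angular sector of width θ(w̃)
  through the full radial thickness, which honors the normalization of w
  exactly (the carved volume fraction of the calcium is exactly w·l). An
  alternative prismatic-box mode carves a true rectangular strip of chord
  width w̃ along the defect bisector (restricted to the bisector's
  half-space so a 270° arc is never carved on the far side); its volume
  comes from a planar boolean and is validated against voxel counting.

The lumen tapers from healthy to stenotic over a 2 mm cosine band just
outside the lesion (the taper length is a modeling choice; the interior of
the lesion is uniformly stenosed). Angles are degrees with the arc bisector
at 12 o'clock; z runs along the axis from the proximal end, u = z/L_a.

Connectivity of the carved calcium (one fragment for sided/centered, two
for through) is measured, not asserted: the (θ, z) occupancy at r_c is
rasterized and labeled with `scipy.ndimage`. Surface meshes are produced by
voxelizing the semi-analytic solid and running marching cubes, which
guarantees closed shells and preserves fragment topology; volume export
writes the labeled voxels as VTK hexahedra. Default voxel pitch is 0.15 mm
(configurable); this resolves the 0.1 mm soft rim adequately for export
purposes while keeping meshes small.

## Constitutive models

Material-point evaluators, not finite-element subroutines:

| component | model | parameters |
|---|---|---|
| lipidic plaque | incompressible neo-Hookean, stress cap | C10 = 13.3 kPa, cap 70 kPa |
| calcified plaque | linear elastic, perfectly plastic | E = 44 MPa, ν = 0.3, σ_y = 0.48 MPa |
| media, adventitia | 6th-order reduced polynomial + hardening table | Ψ = Σ C_i0 (I₁−3)^i |
| stent (Pt-Cr) | linear elastic-plastic | E = 203 GPa, ν = 0.3, table (0, 480), (0.35, 1208), (0.62, 1300) MPa |
| balloon | first-order Ogden | μ = 80 MPa, α = −15 |

Uniaxial Cauchy stress uses the standard incompressible reduction
σ = λ dΨ̂/dλ with Ψ̂(λ) = Ψ(λ, λ^−½, λ^−½); every analytic expression is
tested against central finite differences of the energy (≤1e−6 relative
over λ ∈ [0.8, 1.5]).

Two conventions are exposed for the Ogden scale factor. The printed form
2μ/α with α = −15 gives a negative small-strain modulus (3μα < 0), i.e. a
material unstable at the identity; it is kept as an evaluation-only mode
and flagged by `small_strain_modulus`. The default scales by 2μ/α²
(modulus 3μ = 240 MPa), the convention solvers use for stable first-order
Ogden fits. The balloon μ is taken in MPa.

The 1D elastic-plastic path integrator does classic return mapping: trial
stress E(ε − ε_p), yield check against the hardening curve at the
accumulated plastic strain, and a bracketed root solve for the plastic
increment (closed-form f/E when perfectly plastic). Hardening tables
interpolate piecewise-linearly and extend perfectly plastically beyond the
last knot. The capped neo-Hookean lipidic model clips the hyperelastic
stress magnitude at its cap — a deliberate 1D simplification; full
hyperelastic-plastic coupling is out of scope. Calcium's 1D path uses
σ = E·ε (uniaxial-test reading; ν is metadata). Units are kPa for lesion
soft tissue and MPa elsewhere, with the unit carried on each model.

## Outcome metrics

The cascade, in order:

1. **Lumen gain** α(u) = A_a(u) − A_b(u), post- minus pre-stent lumen area
   on a shared normalized axial grid.
2. **Relative lumen gain** Λ: the lesion-window average of α − ᾱ, where ᾱ
   is the intact baseline's gain. The average of the difference is taken
   (not the difference of separately notated averages — the two readings of
   the defining expression coincide on a shared grid anyway). Λ in mm²
   ("absolute" mode) or, by default, as a percentage of the baseline's mean
   gain over the window ("percent_of_baseline"), which is the unit the
   embedded reference table uses.
3. **Influence coefficients** Δ_l, Δ_w: one-parameter finite differences of
   Λ over the {1/3, 2/3} levels, averaged over the two levels of the other
   parameter; the through sub-model has the single width coefficient
   (Λ(w=2/3) − Λ(w=1/3))/(1/3).
4. **Γ** = √(Δ_l² + Δ_w²) (the Euclidean norm; a transcription of the
   formula that squares Δ_l twice is corrected — the norm is what the
   downstream arithmetic uses), and |Δ| for through.
5. **μ** per arc: the three sub-model Γ values combined. The printed score
   values (144 and 192) correspond to the undivided sum of the norms, not
   the mean the defining formula displays; the sum ("as_printed_numbers")
   is therefore the default and the literal mean ("as_printed_formula") is
   selectable.

`reproduce_paper_summary` chains the cascade the way the published summary
tables chain theirs: each Δ is display-rounded (half away from zero, to
integers) before the cross-arc averages and before Γ/μ — reproducing every
printed cell — while the unrounded cascade is carried alongside. The
reproduction checker compares at half a displayed unit (±0.005).

## Synthetic study generator

Because the expansion simulations themselves are not recomputable at desk
scale, their outputs are emulated by a seeded surrogate with known ground
truth, so the metric pipeline is testable end to end:

- A_b(u): π·r_l(z)² from the configured lumen taper — exactly the healthy
  area outside the lesion and 30 % of it inside.
- A_a(u): A_b plus a raised-cosine baseline gain over the lesion
  (amplitude g0 = 0.9·(healthy − stenotic area) ≈ 4.45 mm², so the intact
  post-stent lumen approaches the 3 mm stent's nominal area), plus, for
  defect models, a raised-cosine boost centered on the defect's axial
  footprint (half-width l̃/2 + 1 mm smoothing) with amplitude
  1.0 mm² · w¹ · l^1.5, times 1.6 for through defects — length deliberately
  more influential and arc-splitting defects strongest, mirroring the
  qualitative findings the metrics are meant to detect. Gaussian noise
  (σ = 0.01 mm², homoscedastic) is added to the post-stent areas, floored
  at 1 % of the healthy area (logged if triggered).
- Grids have 401 points; per-model seeds derive from the master seed and a
  CRC-32 of the model identifier, so datasets are bitwise reproducible.

Ground-truth Λ* comes from the noiseless generator; recovery compares each
noisy Λ̂ against Λ* at three propagated standard errors
(SE ≈ 100·σ·√(2/n_w)/mean(ᾱ), the two √ factors from the model and
baseline profiles sharing independent noise). Raised-cosine (C¹) bumps
avoid spurious grid sensitivity.

**What passing recovery does and does not show.** It validates the metric
implementations (linearity, windowing, the Δ/Γ/μ arithmetic, seeding) and
their noise robustness. It does not validate the surrogate's functional
form against real mechanics: the w^a·l^b response is a stand-in, real
lumen-gain profiles are not raised cosines, real noise is neither Gaussian
nor homoscedastic, and the embedded reference Λ table remains a fixture
input, never a simulation target.

## Numerical choices

- Geometric predicate tolerance 1e−9 mm; display rounding half away from
  zero; full precision retained internally everywhere.
- Degenerate inputs are rejected with named bounds (chords longer than the
  diameter, w·θ_c > 180°, defects wider than the arc, non-isochoric
  stretch states where incompressibility is required, non-monotone
  hardening tables).
- The reproduction and end-to-end pipelines write JSON manifests with
  SHA-256 digests of every output; reruns under the same seed are
  digest-identical. Exit codes: 0 success, 2 reproduction mismatch,
  1 runtime error.
- Problem sizes in the shipped tests and scripts (voxel pitches
  0.03–0.8 mm, 101–401-point grids, 5–20 replicate seeds) were chosen so
  the full suite runs in well under a minute on one CPU while leaving the
  statistical checks comfortable margins.

## Known limitations

- No finite-element solving, contact, balloon folding, crimping, or
  stress/strain field maps: the constitutive module evaluates material
  points only, and expansion outcomes enter via profiles (real or
  synthetic).
- No fracture or damage mechanics; calcium is elastic-perfectly-plastic.
- Lesions are concentric and idealized; eccentric or patient-specific
  (image-derived) geometries are out of scope.
- The lipidic stress cap and the calcium 1D path are uniaxial
  simplifications; whether the cap applies to Cauchy or nominal stress is
  underdetermined by the source parameters (Cauchy adopted).
- Voxel-based meshing trades boundary smoothness for robustness; meshes
  are staircase approximations at the chosen pitch.
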