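# Methods

This note documents the models and algorithms rsfit implements, the
numerical choices behind them, what the synthetic fixtures do and do not
emulate, and the package's known limitations.

## Map model and Fourier scaling

Maps are real-space grids on orthogonal cells (the practical case for
single-particle cryo-EM, which is P1 with 90° angles; non-orthogonal cells
are rejected at read time). Blur/sharpen multiplies the discrete Fourier
transform by `exp(−B·s²/4)` with `s² = (h/a)² + (k/b)² + (l/c)²` in Å⁻²,
the crystallographic temperature-factor convention; the s = 0 term is
untouched, so the map mean is invariant. Under this convention a point
spike blurred by *B* becomes a real-space Gaussian with `σ² = B/(8π²)`,
which the tests check against a radial-profile fit. Finer-grid resampling
zero-pads the spectrum (band-limited interpolation), leaving values at
original nodes unchanged.

Maps are held in float64: sharpening amplifies high-frequency content by
`exp(|B|·s²/4)` — at 0.8 Å sampling and B = 80 that is ~10¹⁰ — so float32
storage would destroy the blur/sharpen invertibility that the package
guarantees (round-trip RMS < 10⁻⁵ of map RMS). Files are still written as
MRC mode 2 (float32), the exchange format.

### Interpolation: two interpolants, deliberately

`interpolate_density` (scoring, blob navigation, validation) is plain
trilinear interpolation: cheap, local, and exactly what the contract
states. The refinement engine and the backrub hypothesis scorer, however,
evaluate density through a C²-continuous cubic B-spline representation of
the same grid (coefficients via `scipy.ndimage.spline_filter`, value and
gradient as exact derivatives of one smooth function). The reason is
structural, not cosmetic: a piecewise-*linear* interpolant attains its
local maxima on grid nodes, so gradient-based refinement against it snaps
atoms toward nodes (a ~0.2 Å systematic artefact at 0.8 Å spacing) and
hypothesis ranking prefers node-aligned poses. Points outside the grid
contribute zero value and zero gradient in both schemes.

## Refinement target

```
total(x) = Σ_classes w_class · E_class(x) − w_map · Σ_i occ_i · Z_i · ρ(x_i)
```

Lower is better. Per class (σ-scaled squared residuals unless noted):

* **bonds / metal-link bonds**: `((d − d₀)/σ)²`.
* **angles**: `((θ − θ₀)/σ)²` in degrees.
* **torsions**: nearest periodic image, `(Δφ_min/σ)²`. Torsion restraints
  are generated (periodicities drive the flip tool) but their refinement
  weight defaults to 0 — restraining χ angles to a single target would
  bias rotamers, and the backbone is already held by bonds/angles/planes.
* **planes**: squared distances to the best-fit (SVD) plane. The analytic
  gradient `2dᵢn/σ²` is exact by the envelope theorem: the fitted plane
  minimises the objective, so derivatives through the plane parameters
  vanish.
* **chiral volumes**: `((V − V₀)/σ)²` with `V = u₁·(u₂×u₃)`; keeps Cα (and
  Ile/Thr Cβ) centres in the L/correct configuration.
* **nonbonded**: `((r_min − d)/0.2)²` for `d < r_min`, with
  `r_min = 0.85·(r_vdw,i + r_vdw,j)` and 0.80 for N/O–N/O pairs (potential
  hydrogen-bond partners); 1-2, 1-3 and 1-4 pairs and metal-linked pairs
  are excluded. The scale factors were chosen so that ideal helical and
  strand geometry is contact-free (an ideal model must score ~0) while
  genuinely misplaced atoms are penalised.
* **Geman–McClure self distance restraints**: `z²/(1+αz²)` with
  `z = (d − d₀)/σ`, `d₀` the distance in the reference model. Harmonic as
  `α→0`, bounded by 1/α — a robust loss that keeps neighbouring atoms
  moving coherently without letting a few bad pairs dominate. Defaults:
  α = 0.01, σ = 0.3 Å, limit 4.2 Å (6–7 Å when longer-range coupling is
  wanted, e.g. for side-chain-less models). σ reflects the positional
  uncertainty of a start model at the domain-fitting stage; a much smaller
  σ (e.g. 0.1 Å) turns the self restraints into anchors to the start
  model's own errors and measurably degrades recovery from coordinate
  noise.

All gradients are analytic (the dihedral gradient uses the standard
rigid-rotation decomposition; every term is finite-difference-checked in
the tests to ≤ 10⁻⁵ relative). Minimisation is L-BFGS-B over the free
(zone) atoms with fixed anchors outside the zone still contributing to
boundary-crossing restraints; the line search guarantees the final total
never exceeds the initial one. `map_weight` defaults to 10: large enough
to dominate coordinate noise, small enough to limit the systematic shift
that overlapping atom Gaussians induce in a sum-of-density target (each
atom feels its neighbours' tails; the equilibrium offset grows with the
map weight).

## Jiggle fit

`n_trials` random rigid transforms (axis uniform on the sphere, angle
uniform in [0, max_rot], translation components uniform in ±max_trans,
pivot at the fragment centroid) are scored with the occupancy- and
Z-weighted density sum; the best `n_keep` are polished by derivative-free
(Powell) rigid-body maximisation; the winner replaces the fragment only if
it strictly beats the starting score. Defaults 400 trials / 30° / 6 Å /
keep 20. Trials are scored independently (order-independent contract), and
the whole procedure is bit-reproducible for a fixed seed. Blurring the map
first (200 Å² is typical) widens the attraction basin of each hypothesis;
the workflow test recovers a 4 Å + 20° displacement to < 0.1 Å.

## Backrub rotamer fitting

For residue *i*, the moving set is exactly: all atoms of residue *i*, C
and O of residue *i−1*, N of residue *i+1*. Hypotheses are rigid rotations
of this set about the Cα(i−1)→Cα(i+1) axis, default ±10° in 21 steps. An
optional second stage (default on) counter-rotates each flanking peptide
about its own Cα–Cα vector to bring the carbonyl O (and next amide N) back
toward their original positions, in closed form (the optimal back-angle is
an `atan2` of projections). Because N, CA, C of residue *i* move rigidly,
its τ angle is exactly invariant; the τ statement therefore refers to the
*flanking* residues, where the measured median |Δτ| over the ±10° sweep on
an ideal tripeptide is ~1.6°.

On each hypothesis backbone, every library rotamer is built by internal
coordinates (NeRF) from dictionary bond lengths/angles with the rotamer's
χ values; the measured χ dihedrals of the result reproduce the library
values to < 0.1°. Score = `w_d·density − w_c·clash` with
`clash = Σ max(0, r_min − d)²` against environment atoms within ~11 Å
(bonded junction pairs excluded; no symmetry mates), both weights 1.0 by
default. Replacement happens only on strict improvement over the current
atoms' score under the same scorer. Rotamer priors carry no secondary
structure dependence.

## Registers, flips, surgery

* **Nudge register**: residue *i* in the zone takes the residue *type* of
  residue *i − offset* (side chain rebuilt at the most probable rotamer on
  the existing backbone; zone edges without a source are stubbed at Cβ),
  then the zone is refined against the map with self distance restraints
  generated from the pre-shift backbone. Re-threading the sequence (rather
  than sliding coordinates) was chosen because it yields deterministic,
  directly comparable hypotheses; the inverse nudge restores the
  assignment.
* **Torsion flips**: deltas are all nonzero multiples of 360°/period
  mapped into (−180°, 180°] (period 3 → ±120°, period 2 → 180°); period-1
  torsions fall back to {180°} so every rotatable bond has a flip. The
  bond's covalent graph is split; the smaller side moves (the larger under
  `reverse`); ring bonds are refused.
* **Fragment surgery**: selections use the `//CHAIN/START-END[/ATOM]`
  dialect with inclusive 1-based ranges. Replace overwrites positions/B/occ
  of matching atoms only; merge allocates fresh chain ids
  (A–Z, a–z, 0–9, then two-character ids); ligand merging picks the chain
  with the minimum atom–atom distance (ties to the lexicographically lower
  id) and numbers the ligand max+gap (gap 1 by default — the numbering
  headroom is a parameter because conventions differ between labs).
* **Metal links**: LINK records whose endpoints are a metal and an N/O/S
  atom produce bond restraints with element-pair targets from a small
  built-in table (Zn–N 2.08, Zn–O 2.10, Zn–S 2.32, Mg–O 2.08, Fe–S 2.30,
  Ca–O 2.38, …; any entry overridable in the config file; unlisted pairs
  default to 2.20 Å); the pair is simultaneously removed from nonbonded
  generation. Full ligand-field atom typing is out of scope, so these
  targets are first-shell typical values, not chemistry-aware ones.

## Dictionaries and libraries

The embedded monomer dictionary covers the 20 amino acids. Its bond,
angle, plane and chiral targets are *measured* from a single canonical
build of each residue type (Engh–Huber-style backbone values; aromatic
rings constructed as exactly closing polygons), which guarantees that an
ideal-geometry fixture scores zero distortion against its own dictionary —
the self-consistency every recovery test rests on. External ligand
dictionaries are read from the mmCIF restraint dialect
(`_chem_comp_bond/_angle/_tor/_plane_atom/_chir`); a toy ligand
(meta-chloro propylbenzene) ships as data for tests and examples, and a
writer can export any entry in the same dialect.

The rotamer library is a compact tab-separated table (type, name, prior,
χ1–χ4) with 1–4 common rotamers per type — a reduced set in the spirit of
the penultimate-library compilations, with approximate priors. The format
is documented precisely so a full library can be dropped in. Proline has a
single entry (ring pucker is not searched), leaving 17 types with ≥ 2
rotamers.

The Ramachandran tables are synthetic: peak-normalised wrapped-Gaussian
mixtures centred on the classical favoured regions (α at (−63°, −43°), β,
polyproline-II, left-handed α), with class variants — Gly symmetrised
under (φ,ψ) → (−φ,−ψ), Pro confined in φ, pre-Pro with an extra basin near
(−130°, 75°), Ile/Val weighted toward β. Cutoffs are relative
probabilities: preferred ≥ 0.02, allowed ≥ 0.002 of peak, both
configurable, 5° grid. These surfaces reproduce the qualitative layout of
database-derived tables (ideal helices and strands are "preferred";
torus-wrapped lookups are bilinear) but are *not* fitted to structural
data — absolute outlier percentages on real models should not be compared
against published statistics. pre-Pro takes precedence over the type
classes (a residue before proline is classed pre-Pro even if Ile/Val).

## Synthetic fixtures: what they emulate, what they don't

Polypeptides are built by internal coordinates at exact ideal geometry
(helix φ,ψ = −57°,−47°; strand −120°,120°; ω = 180°; side chains at the
top rotamer). Maps are sums of single-Gaussian atoms,
`ρ(x) = Σ occ·Z·exp(−|x−x₀|²/2σ²)` with `σ² = B/(8π²)`, default B = 40 Å²
and 0.8 Å sampling for a ~3 Å-resolution look, amplitude-normalised so a
unit-occupancy carbon peaks at Z = 6. This gives closed-form checks (the
grid integral, the synthesis/blur commutation up to the analytic
`(σ_B/σ_{B+ΔB})³` volume factor) and is deliberately non-physical: no
multi-Gaussian scattering factors, no solvent, no noise, no anisotropy, no
missing wedge. Passing recovery tests therefore demonstrates the
*algorithms* converge on well-posed input; they do not calibrate expected
accuracy on experimental maps. One discretisation effect is worth knowing:
the interpolated field's maximum sits slightly off the true atom centre at
coarse sampling, so exact score ties (e.g. "the truth pose is not
replaced") are only guaranteed on finer grids (≤ 0.6 Å in the tests).

Problem sizes in the test suite were chosen to keep the whole run at a few
minutes on one core: 20-residue chains, 400 jiggle trials over 20 seeds,
tripeptides for per-residue operations. All generators are bit-reproducible
for fixed seeds.

## Numerical choices and degenerate inputs

* Dihedral convention: IUPAC signed, range (−180°, 180°]; the hand-checked
  4-atom case and the sign of the analytic gradient are pinned by tests.
* Angle gradients guard against sin θ → 0; NeRF placement handles collinear
  reference frames with a deterministic fallback axis.
* Blob walk: default step = half the minimum grid spacing (Nyquist-safe);
  a front point already above contour starts accumulating immediately (the
  walk is treated as starting inside a blob).
* Rotamer-analysis ties (χ equidistant) go to the lower-index, i.e. more
  probable, rotamer; merge-ligand chain ties to the lower chain id.
* Empty selections: fragment copy warns and returns an empty structure;
  restraint generation and refinement treat them as errors.
* Altlocs are carried through I/O and surgery as a unit; refinement and
  fitting operate on all atoms given (no per-altloc machinery).

## Limitations

No de novo chain building (alignment insertions are recorded, not built);
no anisotropic B or occupancy refinement; no symmetry mates anywhere
(cells are P1 orthogonal); no torsion-space refinement; no
secondary-structure-dependent rotamer priors; no structure-factor (mtz)
output; carbohydrate building, external homolog-restraint import and 2D
ligand depiction are out of scope. The metal target table is element-pair
based, not atom-type based. Reports are TSV/JSON; plotting is left to the
caller.
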