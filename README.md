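# rsfit

Headless real-space model building, refinement and validation for
macromolecular structures in density maps — the batch-mode core of the
interactive fitting workflow used with cryo-EM reconstructions (2.5–4 Å)
and crystallographic maps.

## Who this is for

Structural biologists (and pipeline authors) who need to place a homolog
domain into a map, refine it, swap its sequence, fix side chains and
validate the result — without a graphical session. Everything is driven
from Python (`import rsfit`) or the thin `rsfit` command-line tool, and
every algorithm is exercisable on synthetic fixtures with no downloads.

## What it does

* **Maps** — MRC/CCP4 I/O (orthogonal cells), Fourier **blur/sharpen**
  (multiply structure factors by `exp(−B·s²/4)`; positive *B* smooths,
  negative sharpens; blurring a point by *B* gives a Gaussian with
  `σ² = B/(8π²)`), multi-*B* series from one transform, finer-grid
  resampling, trilinear density scoring, and **blob navigation** (walk a
  view ray, recentre on the density-weighted mean of the first
  above-contour segment).
* **Fitting** — stochastic **jiggle fit** (random rigid hypotheses scored
  against the map, best *k* rigid-body refined, accepted only on strict
  improvement) and local rigid-body refinement.
* **Refinement** — real-space minimisation of
  `E = Σ restraints − w·Σ occ·Z·ρ(xᵢ)` over a zone, chain or domain, with
  bonds/angles/torsions/planes/chirals/nonbonded restraints from an
  embedded monomer dictionary and **self Geman–McClure distance
  restraints**: `ρ(z) = z²/(1+αz²)`, harmonic for small deviations,
  saturating at 1/α so outlier pairs cannot dominate, which makes atoms
  move in a concerted way.
* **Side chains** — **backrub rotamer fitting**: rotate the residue plus
  the C,O of the previous and N of the next residue about the
  Cα(i−1)–Cα(i+1) axis, build every library rotamer on each hypothesis by
  internal coordinates, score density minus clashes, accept on strict
  improvement. The central τ (N–CA–C) angle is exactly preserved and the
  flanking τ change is small (median < 2° over ±10°).
* **Editing** — fragment copy/replace, molecule merging with fresh chain
  ids, proximity-based ligand merging, register **nudging** (shift residue
  identities along a zone to test out-by-one hypotheses), sequence
  **align-and-mutate** from an external FASTA alignment, **torsion flips**
  (±120°/180° from dictionary periodicity), metal LINK bond restraints.
* **Validation** — Ramachandran reports with the general / Ile-Val / Gly /
  Pro / pre-Pro classes, **Kleywegt** NCS-chain comparison (top-50 most
  distant φ/ψ pairs), rotamer probabilities, mean/median B factors,
  per-residue density fit, dictionary-based ligand distortion z-scores.

## Worked example

`examples/01_fit_domain_workflow.py` builds a 20-residue ideal helix and
its synthetic 3 Å-style map, displaces the model by 4 Å + 20°, then runs
the standard two-stage workflow — jiggle fit on a 200 Å²-blurred map,
chain refinement with self distance restraints (limit 6 Å) on the working
map:

```
start:        RMSD to truth = 4.66 A
after jiggle: RMSD to truth = 0.08 A (density score 1479)
after refine: RMSD to truth = 0.047 A (total score -55009)
```

The blurred map's wide attraction basin lets the rigid search find the
pose; restrained refinement then settles the model to a fraction of the
voxel size. The other examples cover backrub side-chain fitting,
validation reports, fragment surgery, and ligand flips:

```sh
python examples/02_backrub_side_chain.py
rsfit fixtures helix --n 20 helix.pdb
rsfit fixtures map helix.pdb helix.mrc
rsfit map blur --b 200 helix.mrc blurred.mrc
rsfit validate rama helix.pdb
```

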