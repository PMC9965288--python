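# Methods

This note records the models, conventions and numerical choices behind
`tmdkit`, and what the synthetic generators do and do not emulate.

## Coordinate and numbering conventions

All internal math is in Ångström; the PDB native unit wins wherever a
quantity could be quoted in nm. Author (receptor) residue numbering is
the only numbering exposed — residue 919 in an input file is residue
919 everywhere in the API. Altloc handling keeps the highest-occupancy
conformer (ties to the first seen); HETATM solvent is skipped on read.

## Helix axis

The axis of a residue span is computed in two steps. Each interior Cα
is first displaced onto its local helix centre: for an ideal helix the
second difference `p[i-1] + p[i+1] − 2·p[i]` points exactly at the
axis, so `p[i] + r·û` (with the canonical Cα radius r = 2.3 Å) lies on
it. The principal axis (first right singular vector) of these
wobble-corrected points through their centroid is then the helix axis,
sign-fixed from the N- to the C-terminus. A plain principal-axis fit
on raw Cα positions is biased by up to ~2° on spans shorter than two
full turns (the azimuthal coverage is uneven); the centre displacement
removes that bias exactly on ideal geometry, which matters for the
7-residue N-terminal helix of IRR. Fitting requires ≥ 4 Cα positions.

Angle conventions: tilt against the membrane normal uses |cos| and is
reported in [0°, 90°] (an axis and its negation tilt identically);
inter-segment (kink) angles use the signed N→C orientations of both
axes and live in [0°, 180°].

## Segments and end-to-end distances

Built-in helical spans (receptor numbering): InsR A955–G960 /
P961–L979 with end pair A955–R980; IGF1R F933–L940 / P941–V948 plus a
C-terminal helix L951–R960 for the glycine-hinge kink, end pair
F933–R960; IRR G919–T925 / V929–K946, end pair G919–K946. All are
user-overridable. End-to-end distances are Cα–Cα — the conventional
choice for end-to-end measures; heavy-atom or terminus-atom variants
would differ by ~1 Å and can be had via the `atom_name` argument.
Reports carry both per-model values and ensemble means, since either
could be meant by a "~" figure.

## Ideal-helix template and RMSD

The template places backbone atoms on a helical wheel with rise
1.5 Å/residue and twist 100°/residue; per-atom (radius, phase, axial)
offsets are chosen to reproduce standard backbone bond lengths to
within a few hundredths of an Å (Cα radius 2.3 Å). `rmsd_to_ideal`
slides a window (default 7 residues) along the segment, superposes its
backbone onto the template by least squares (Kabsch), and assigns each
residue the RMSD of the best window covering it. Residues with missing
backbone atoms are NaN and their windows are skipped.

## Two-state classification

Per ensemble model the classifier computes (kink angle, end-to-end
distance), standardizes both features, and runs 2-means with
deterministic initialization at the models of minimum and maximum kink
angle (≤ 100 iterations; exact distance ties assign to the
lower-initialized cluster). The lower-mean-angle cluster is labelled
"straight" (I), the other "bent" (Γ). An ensemble of identical models
returns a single cluster with a warning flag rather than an error.
The procedure has no random state and is invariant to model order.

## MHP surface maps

MHP(j) = Σᵢ fᵢ·exp(−dᵢⱼ/α) with decay length α = 2.0 Å by default
(configurable; the literature on the method does not pin a single
value). Constants fᵢ are a united-atom table in the spirit of the
Ghose–Crippen atomic log p typology, written for this package:
aliphatic/aromatic carbons positive, polar N/O negative, hydrogens
folded into their heavy atoms. The absolute calibration is approximate
and user-replaceable; every analysis and test in the package relies on
orderings and equivariances, not absolute log p values. Unknown
(residue, atom) pairs are a hard error, never a silent zero.

The surface is a Shrake–Rupley style dot sampling: each atom's sphere
(van der Waals radius + 1.4 Å probe) is dotted on a golden spiral at
the requested density (default 2 points/Å²); dots inside a neighbour's
expanded sphere are discarded; each surviving dot is owned by its atom
and carries an equal share of that sphere's area.

Projection: a point's azimuth is measured in the plane normal to the
helix axis from a reference direction — by default the projection of
the segment's first-residue Cα, anchoring the map phase to the
sequence. Cells (default 10° × 1 Å) hold area-weighted means; empty
cells are NaN with zero weight, and frame averaging is weight-aware
(a cell is empty only if empty in every frame).

## Lipid density and contrast

Lipid atoms (tail carbons by default) are binned per frame into
annular sector cells (radial shell × azimuth × axial shift) of a
cylinder aligned with that frame's helix axis — per-frame axes because
the helix tilts over a trajectory. Density is counts/(cell volume ×
frames) with the exact sector volume ½(r₂²−r₁²)·Δθ·Δz, so
Σ density·volume·frames reproduces the integer count of in-range
atom-frames. Default shells 5–8, 8–11, 11–14 Å with 15° × 1.5 Å bins;
the radii are stated qualitatively in the source figures, so these are
package defaults, exposed in the grid spec. The axial origin can be
pinned to a lab point (e.g. the bilayer midplane) via `z_origin`.

`contrast_score` = max cell density / shell mean density (≥ 1). It is
the package's quantitative surrogate for visually "darker" immobilized
lipid patches: uniform lipid motion gives ≈ 1 plus counting noise,
pinned lipids concentrate counts in a few cells and push it well above
3 at a 30% immobilized fraction.

## NMR metrics

Δδ¹Hᴺ = δ_obs − δ_rc with the random-coil ¹Hᴺ table of Wishart et al.
(J Biomol NMR 5, 67–81, 1995); proline has no amide proton and is
undefined. Negative Δδ¹Hᴺ flags lengthened HN⋯OC hydrogen bonds
(locally destabilized helix).

The cross-correlation rate is estimated as η = ln(I_ref/I_att)/(2Δ)
with Δ = 10.8 ms by default, and first-order noise propagation
σ_η = √((σ/I_ref)² + (σ/I_att)²)/(2Δ). τ_R solves
η(τ) = C·P₂(cosθ)·[4J(0) + 3J(ω_N)], J(ω) = (2/5)·τ/(1+ω²τ²), where
C is the product of the ¹H–¹⁵N dipolar coupling constant
(μ₀/4π)·ħγ_Hγ_N/r³ and the ¹⁵N CSA term γ_N·B₀·Δσ/3. Magnitudes of
γ_N and Δσ are used so η > 0 for τ > 0 under either sign convention.
Defaults: 600 MHz, Δσ = −170 ppm, r_NH = 1.02 Å, θ = 17°, all
configurable since the acquisition constants of any given experiment
vary. The forward map is strictly increasing in τ, so the inversion is
a bracketed Brent root find on (0, 200 ns], tolerance 1e−4 ns; rates
above the 200-ns ceiling are an error naming the bound. σ_τ =
σ_η/|dη/dτ| by a central difference. Segment averages are unweighted
means over defined residues with the count reported. Experimental τ_R
values cannot be reproduced bit-for-bit without the raw spectra and
per-sample acquisition constants; the package therefore validates this
path by parameter recovery through the forward model. HSP and S²
profiles are produced by external chemical-shift tools and are only
ingested (validated to [0, 1]) for joint reporting.

## Synthetic generators

`make_helix` builds backbone (N, Cα, C', O) helices on the ideal wheel;
a hinge is a rigid rotation of everything C-terminal of the kink
residue about an in-plane axis through that residue's Cα. The axis
azimuth (`kink_direction_deg`) is a real degree of freedom: it sets the
direction the helix bends toward and hence how much a bend shortens
the end-to-end distance. Kinks are rigid rotations, not dihedral
remodelling — sufficient for axis/angle recovery, not for torsion
statistics. An optional coarse side-chain mode adds a Cβ bead plus one
residue-specific "tip" heavy atom (e.g. Ser Oγ, Leu Cγ), enough to give
helices azimuthal hydrophobicity structure for surface-map tests.

`make_two_state_ensemble` mixes straight and bent specs with per-model
hinge-angle jitter and per-model coordinate noise from child seeds,
returning ground-truth labels.

`make_bilayer_trajectory` surrounds a rigid helix with coarse
5-bead lipid chains (64 per leaflet by default): heads at ±12.6 Å,
tail beads spaced 2.8 Å toward the midplane, each bead bobbing
uniformly within ± half a spacing so the time-averaged axial
distribution tiles the leaflet uniformly. Mobile lipids do a lateral
Gaussian random walk (step 3 Å/frame) between the helix-exclusion
radius (5 Å) and the box radius (22 Å); an `immobilized_fraction` of
them instead stays within 1 Å of anchors placed at a chosen azimuth
against the helix surface. This emulates exactly one observable — the
azimuthal/axial concentration of immobilized lipid density — and none
of the physics: no packing, no chemistry, no leaflet coupling, no
protein flexibility. Passing density tests therefore demonstrates the
correctness of the binning, conservation and contrast machinery, not
membrane realism.

`make_relaxation_table` applies the forward intensity model
I_att/I_ref = exp(−2Δ·η(τ)) with multiplicative Gaussian noise on both
intensities and records the absolute noise level used.

### Stand-ins for the deposited ensembles

`standin_ensemble` builds 20-model ensembles for InsR, IGF1R and IRR
from the published construct sequences and hinge geometry: IRR as a
50/50 straight/bent mixture (26° / 70° at P928), InsR as a single
family bent 26° at P961, IGF1R bent 30° at P941 with a 10° kink at the
G949–G950 hinge. Bend azimuths are fixed so the hinge geometry also
reproduces the published end-to-end distances (a rigid ideal helix
bent 26° at P961 spans ~37–39 Å between A955 and R980 depending on
bend direction). Coordinate noise of 0.25 Å and hinge-angle jitter of
a few degrees stand in for genuine NMR ensemble spread. These objects
are synthetic: they encode the printed characterization of the
deposited structures, not their coordinates, and every number computed
from them is a construction-recovery result.

## Pipeline determinism

Run configurations are JSON with unknown-key rejection; every output
file carries a SHA-256 hash of the analysis-relevant configuration
(the output directory is excluded), so reruns on identical inputs are
byte-identical. All generator randomness flows from explicit seeds.

## Problem sizes

Defaults used by the test suite and the acceptance script: 20-model
ensembles; 1000-frame bilayer trajectories with 128 lipids (640
beads); 500-frame RMSF checks; 1000-trial noise-recovery loops;
surface sampling at 2 dots/Å². These sizes give sub-percent Monte
Carlo error on the quantities checked while keeping any single
analysis in the tens of seconds on one CPU.

## Known limitations

- The hydrophobicity constant set is approximate and uncalibrated
  against experimental log p; only orderings should be interpreted.
- Axis fitting assumes a locally helical span; on random coil the
  "axis" is only the least-squares line of smoothed points.
- The lipid generator has no notion of bilayer physics (see above).
- Trajectory dialects are text-based (concatenated multi-model PDB and
  a per-frame xyz table); binary formats would slot in behind the same
  reader contract but are not implemented.
- mmCIF and NMR-STAR inputs are out of scope; shift and intensity
  tables are ingested as TSV.
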