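# Methods

## Scope and model

`fibrilgeom` treats an amyloid fibril model as a stack of molecular
layers: each layer holds one subunit (chain) per protein stack, and
consecutive layers are related by one helical step — a rotation ω (the
twist) about the fibril axis plus a translation *r* (the rise) along it.
All analyses assume the model is a finite segment of such a helix with
the layers present as explicit chains; no symmetry expansion from
deposited helical parameters is performed.

Conventions used throughout:

- Angles in degrees, wrapped to (−180°, 180°]; the wrap maps both seams
  to +180° so the value is unique.
- The axis is oriented so the rise is positive.  With that orientation
  the twist sign alone carries handedness: ω > 0 (counterclockwise
  viewed from the +axis tip, right-hand rule) is a right-handed helix.
- Crossover distance *c* = (180°/|ω|)·*r* (half turn), pitch *p* = 2*c*
  (full turn).  These are identities of the reported twist and rise, not
  independent measurements.
- Author residue numbering is used verbatim, because fibril structures
  are discussed in precursor coordinates (Ser2, Tyr29, ...).
- Lengths are Å internally; crossover, pitch and width are reported in
  nm as is customary for fibril-scale quantities.

## Dihedrals and the δ statistic

Φ and Ψ follow the IUPAC definitions, computed per chain after sorting
by residue number; a C(i)–N(i+1) distance above 2.0 Å is treated as a
chain break, and residues flanking breaks or missing backbone atoms get
undefined angles (skipped with a warning, never an error).

δ = Ψ + Φ measures the signed distance of a residue from the −Φ = Ψ
Ramachandran diagonal.  For β-sheet residues, δ > 0 (right of the
diagonal) corresponds to a left-hand twisted sheet and δ < 0 to a
right-hand one.  The summary reports the arithmetic mean of the wrapped
δ values and the sample SD (n−1 denominator; 0 when n = 1).  A plain
arithmetic mean is appropriate because β-region δ values sit far from
the ±180° seam; the package does not use circular statistics, which is a
documented limitation if it is ever applied to angle sets spanning the
seam.  Residues with δ exactly 0 lie on the diagonal: they count toward
n but toward neither side — a measure-zero case fixed for determinism.
The categorical call is *left* iff mean δ > 0 **and** more than half the
residues lie on the δ > 0 side, *right* for the mirror condition, else
*indeterminate*; requiring both statistics to agree keeps the call
robust against a few outlier residues.

δ statistics are pooled over all chains of a stack (with the per-chain
breakdown available through the per-residue records); which single chain
a publication used for its quoted value is generally not stated, and
pooling is both more stable and order-invariant.

## β flagging and strand segmentation

The default β criterion is a dihedral window, Φ ∈ [−180°, −30°] and
Ψ ∈ [60°, 180°] ∪ (−180°, −150°] (the union lets the β region cross the
±180° seam).  A dihedral window is used instead of DSSP-style H-bond
assignment deliberately: in a cross-β fibril the H-bond partners of a
strand are in the *adjacent layers*, so an isolated chain has no
intra-chain sheet H-bonds at all.  A simplified cross-layer mode
(`hydrogen_bond_beta`) flags a residue when a backbone N–O contact to
the same-numbered residue of an axially adjacent chain falls below a
cutoff (default 3.5 Å, the usual heavy-atom H-bond distance); on the
idealized generator fibrils, which stack strands at the cross-β spacing
without optimizing carbonyl orientations, these contacts are
systematically longer (≈5 Å), so tests of that mode pass an explicit
larger cutoff.  Users can also bypass assignment with an explicit
segments file.

Strand segmentation merges runs of β residues separated by at most
`max_gap` non-β residues (the merged segment spans the gap) and drops
merged runs shorter than `min_length`.  Defaults `min_length=2`,
`max_gap=1` reproduce the visual convention of ignoring single-residue
interruptions; both are exposed because published strand counts (β1–β8)
are read off figures whose boundaries are not printed, making the count
parameter-sensitive.  Numbering gaps are hard breaks.

## Helical parameters

For every stack and every consecutive layer pair, the shared-residue Cα
sets are superposed.  The reported twist and rise come from a fit in
which the rotation is **constrained to the fibril axis**: the in-plane
rotation angle is the 2-D Procrustes optimum of the cross-section
projections and the rise is the mean axial shift.  This matters for
noisy models — fibril subunits are nearly planar, so a free 3-D Kabsch
rotation has a poorly determined out-of-plane component which, acting on
a centroid far from the axis, contaminates both twist and rise.  The
free Kabsch fit is still computed as a model check: if the constrained
residual exceeds max(2×, +0.5 Å) of the free residual — or, for
essentially rigid steps (free RMSD < 0.05 Å), if the free rotation axis
deviates more than 10° from the fibril axis — the model is not a simple
helix about the stated axis and the function refuses.  Twist and rise
are means over all steps and stacks; per-step values are retained so
non-uniform models are visible.

Estimator accuracy at the conditions used in the tests and the
acceptance script (30-residue chains, 6 layers): exact to 1e-6 without
noise over twists ±0.5°…±4° and rises 2.4/4.8 Å; with 0.3 Å i.i.d.
coordinate noise the mean absolute errors are ≈0.02°/0.02 Å, within the
0.1°/0.05 Å bounds asserted.

Model width is the maximal pairwise heavy-atom distance in the
cross-section plane plus a 2 × 1.7 Å atomic-radius margin (convex hull
of the projection, with a brute-force fallback for degenerate point
sets).  A model-derived width is a lower bound on micrograph widths,
which include disordered regions invisible in the model; it is reported
for context only.

## Layer and stack decomposition

Chains are grouped into stacks first: by residue-range signature when
the stacks are non-equal, otherwise by deterministic 2-means clustering
of cross-sectional centroids (seeded with the farthest pair).  Layers
are then the per-stack axial ranks, aligned across stacks by nearest
axial position.  The obvious alternative — 1-D clustering of axial
centroids into layers — fails exactly for the staggered-stack geometries
this package targets: with a half-rise stagger the chain centroids are
evenly spaced and show no layer gaps.  The decomposition refuses, with a
diagnostic listing axial centroid positions, when stack clusters are not
separated, when the two clusters have inconsistent sizes, or when the
within-stack axial spacing is strongly bimodal (max gap > 2 × min gap —
the signature of two interleaved stacks merged into one).  Two exactly
superposed stacks staggered by exactly half a rise are genuinely
indistinguishable from a 1-start helix of single chains and are read as
such.  When the two stacks are non-equal, the stack of shorter subunits
is labelled A (matching the naming for the vascular AA fibril); for
equal stacks the label is fixed by lexicographic chain order.

The axis defaults to +z (`as_deposited_z`), correct for deposited
fibril models.  `pca_estimate` takes the principal direction of the
per-chain Cα centroids; it is exact for untwisted test geometries and
approximate for twisted fibrils whose centroid track precesses — the
deposited-frame mode is the default for that reason.

## Axial register and stagger

The register of residue *a* vs residue *b* is the signed difference of
their Cα coordinates along the axis (negative = *a* lower, with
"lower/higher" defined by the rise-positive orientation).  Values are
reported for every chain, since the two stacks of a C1 fibril differ.
The stack stagger is the axial offset between the two stacks' reference
Cα in the central layer, reduced modulo the rise into (−rise/2, rise/2];
±rise/2 indicates half-layer stagger (the pseudo-2₁ geometry).  The
rise for the reduction is the median inter-layer centroid spacing, which
is robust to noise and needs no helical fit.

## Charges

Charge assignment is a per-residue model: integer charges (acids −1
when pH > pKa, bases +1 when pH < pKa; at pH 7.4 this gives Asp/Glu −1,
Arg/Lys +1, His/Cys/Tyr 0, N-terminus +1, C-terminus −1) or fractional
Henderson–Hasselbalch occupancies; the two agree to < 0.002 e once the
pH is 3 units from every pKa.  The pKa table (Asp 3.65, Glu 4.25,
His 6.00, Cys 8.30, Tyr 10.07, Lys 10.53, Arg 12.48, termini 9.00/2.00)
is overridable.  This deliberately replaces a Poisson–Boltzmann
treatment: the polymorph-distinguishing observables — net charge per
molecular layer and whether the cross-sectional charge distribution is
balanced — are already determined at this level.  For the SAA1.1
fragment layers the integer model at pH 7.4 gives −2 e per vascular
layer (subunits 2–40 + 2–69) and 0 e per glomerular layer (2 × 2–55);
the terminal charges cancel pairwise (+1 −1 per chain), so including or
excluding termini reproduces the same net values — both policies are
surfaced and the acceptance script records both.  Modeled chains are
proteolytic fragments with genuinely free N-termini, while the apparent
C-terminus of a chain truncated at the fibril core boundary is an
artifact of disorder; `include_termini=False` is the switch for users
who want the conservative reading.

Charge asymmetry is the first moment Σ qᵢ(rᵢ − centroid) over one
layer, projected onto the cross-section plane, with carriers at
side-chain reference atoms (Asp Cγ, Glu Cδ, Arg Cζ, Lys Nζ, termini at
backbone N/C; Cβ/Cα fallbacks for reduced models) and the centroid at
the layer's Cα center.  The normalized score divides the moment
magnitude by (Σ|qᵢ| × cross-sectional radius of gyration); it is 0 for
any 2-fold-symmetric charge arrangement — in particular a pseudo-2₁
layer cancels almost exactly — and grows toward order 1 as charge
accumulates on one side.  It can exceed 1 for a lone distant charge;
it is a ranking score, not a probability.

## Fragment matching

Theoretical masses are residue-mass sums plus one water (monoisotopic by
default, average masses for low-resolution data), via pyteomics.
Candidates are enumerated over start × end position sets; the default
start is position 2 because AA fibril proteins lack the precursor's
first residue.  Every observed mass is assigned to all candidates
within the ppm tolerance (default 10 ppm), ranked by |error|, ties by
shorter fragment then smaller start; ambiguous assignments are a real
feature of intact-mass data and are reported rather than suppressed.  A
fixed modification offset can be applied to every theoretical mass; no
PTM search is attempted.  With candidates at every possible C-terminus
of SAA1.1, adjacent candidates differ by ≥ 57 Da (≈ 4 orders of
magnitude above the tolerance), so recall of seeded fixtures is 1.0
whenever the injected jitter is below the tolerance.

## Synthetic generator

`build_strand` places N/Cα/C/O/Cβ with ideal bond lengths and angles
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å) and exactly the prescribed
(Φ, Ψ), ω fixed trans; the first Φ and last Ψ are undefined by
construction.  `build_fibril` applies layer transforms about +z;
stack B is staggered axially and, for pseudo-2₁ symmetry, rotated by
180° **plus half the per-layer twist**, which makes the two-stack
assembly an exact screw: with stagger = rise/2 it is a 1-start helix
with twist/2 + 180° per half-step.  Noise is i.i.d. Gaussian per
coordinate, applied after assembly, seeded.

The polymorph presets encode the study conditions: 4.8 Å rise; twist
∓1.66°/layer (giving the ~52 nm crossover); SAA1.1 fragment sequences
2–40/2–69 (vascular, C1, stacks side by side with a half-rise stagger)
and 2–55 (glomerular, pseudo-2₁); uniform β backbones whose δ equals the
reported per-stack means (+12°, +11°, −2°).  Six layers (12 chains)
mirror the deposited-model convention and keep every analysis
sub-second.

What the generator does **not** emulate: real per-residue dihedral
heterogeneity (preset δ SDs are ~0, unlike the ~20–37° of real fibrils),
side chains beyond Cβ (charge carriers fall back to Cβ), turns between
strands (each subunit is a single straight strand, so widths exceed real
cross-sections and strand counts are 1 per chain), sterics and H-bond
geometry.  Passing tests therefore demonstrate estimator correctness on
known ground truth and the sequence-determined charge arithmetic — not
that a deposited structure would yield any particular δ dispersion or
strand count; those analyses run on real models through the same code
paths.

## Parsing and determinism

Structure input goes through gemmi (PDB/mmCIF).  Hydrogens, waters and
non-amino-acid heterogens are dropped; alternate locations resolve to
the highest occupancy, ties by altloc identifier order; nonstandard
amino acids are kept, flagged, and given charge 0.  All pipelines are
deterministic given inputs and configuration: every stochastic element
(generator noise, mass jitter) takes an explicit seed, cluster seeding
is by farthest pair, and the comparison report carries a configuration
hash so any parameter change is visible in the provenance block.
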