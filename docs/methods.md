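# Methods

This note records the models, parameter choices and numerical conventions
behind `granulekit`, and what the synthetic studies do and do not
demonstrate about real data.

## Confidence scoring

The scoring model treats each location keyword as a weak classifier over a
labelled split of the pooled proteome roster. `LocScore(k)` is the
difference between the fraction of curated positives and the fraction of
trial negatives carrying `k`; it lies in [−1, 1], is positive for
granule-typical keywords ("secretory vesicle") and negative for impurity
markers ("mitochondrion", "nucleus"). Interaction partners contribute the
analogous `IntLocScore`, built from their own keyword table, on the
assumption that interactors co-localise; each partner contributes its
keyword set once. A protein's raw confidence is
`N_proteome × (W_loc·ΣLocScore + W_intloc·ΣIntLocScore)`; the linearity in
`N_proteome` encodes that repeated proteomic detection multiplies the
annotation evidence. Raw scores are min–max normalised over the scored
roster, so reported confidences are dataset-relative, not absolute
probabilities. The weight pair is chosen by maximising ROC AUC (midrank
tie handling, equivalent to the Mann–Whitney U statistic) over a user
grid; ties break to the smallest weights, so when one evidence channel is
uninformative the sweep collapses onto the other.

**Caveat**: the positives double as training data; no cross-validation is
applied (the curated set is too small to split meaningfully), so positives'
high scores partly reflect training bias. The scores are a ranking device
for manual review, not calibrated probabilities.

## From abundances to copy numbers

NSAF (abundance ÷ sequence length, renormalised) approximates molar
fraction; multiplying by molecular weight and renormalising gives mass
fraction. Cross-proteome consensus is the mean of per-proteome mass
fractions over the proteomes that detected the protein — computed within
each proteome first, so study-specific metric scales cancel. Outlier
measurements can be excluded per (protein, proteome) before pooling.
Curated proteins absent from every proteome enter at a floor fraction
(default 10⁻⁴ of total mass) so they appear in models without distorting
the budget.

Absolute numbers follow from geometry. The reference granule is a 320 nm
sphere with a 200 nm crystal; the crystal's protein volume occupancy comes
from the unit-cell metadata of the rhombohedral (hexagonal-setting H3)
insulin crystal form: occupancy = z·M_asym/(N_A·ρ·V_cell) with
ρ = 1.22 g cm⁻³, giving 0.686 (0.584 for the monoclinic P2₁ form). The
bundled metadata for the two reference forms is a reconstructed stand-in
(cell constants from the literature; asymmetric-unit weights set for
consistency with the published occupancies) — the occupancy arithmetic,
not the metadata, is the tested component. A 200 nm crystal then holds
round(V·occ·ρ/m_insulin) ≈ 3.63×10⁵ monomers, inside the 2×10⁵–10⁶ range
reported for single granules. The crystal is fixed at 0.8 of the granule's
protein mass; everything else shares 0.2, split 75 : 25 between lumenal
and membrane-bound pools (the lumen dominates ISG protein mass through the
granins and processing enzymes; the share is configurable). Copy numbers
round half-to-even; curated must-include proteins floor at one copy.
Manual exception hooks reproduce the published curation: islet amyloid
polypeptide at 1% of insulin; multi-subunit complexes (vATPase) counted as
the stoichiometry-normalised mean of their subunits.

## Granule geometry and maturation

All compartments are spherical signed distance fields; the membrane is a
5 nm shell. Maturation step s ∈ {1..6} partitions the fixed insulin
complement: proinsulin fraction p = (6−s)/5 falls linearly, the crystal
takes c = 1−p−m, and a transient free-monomer pool m = p(1−p) peaks
mid-pathway and vanishes at both ends (the partition rule between the
stated endpoints is our choice). Crystalline and cleaved insulin leave
their cleavage peptides (C-peptide plus linker dipeptides, 3,580 Da per
monomer) in the lumen, so mature lumens stay peptide-rich — this mass
bookkeeping is what pushes the immature lumen to ≈0.41 g ml⁻¹ and LAC
≈0.40 µm⁻¹. The crystal shrinks with the cube root of its monomer count.

Packing: each lumenal species is placed on its own grid of cells sized to
its bounding sphere, sampled without replacement with sub-cell jitter and
uniform random orientations; a random-close-packing guard rejects requests
above 0.64 of the free volume. Cross-species overlaps are left to the
relaxation step — damped rigid-body displacement along soft repulsive
forces (force ∝ overlap depth, zero beyond contact), with membrane-anchored
species constrained to their shell by projecting out radial displacement
and escapees reflected at the compartment boundary. At the 37.42 nm
imaging voxel, sub-voxel rearrangement is invisible, so the imaging
scenarios build without full relaxation; `relax` is exercised on small
fixtures where its energy descent and convergence are assertable.

Lipids: DOPC with molecular volume 1,150 Å³. The area per lipid is derived
as volume ÷ leaflet thickness (46 Å² at a 2.5 nm leaflet), which makes the
placed lipid volume fill the bilayer shell exactly; the resulting
≈1.36×10⁶ lipids per 320 nm vesicle is ~50% denser than a tension-free
DOPC bilayer (≈70 Å² per lipid) — an idealisation that treats the shell,
including its embedded protein acyl contacts, as solid lipid.

The fitting-library grid spans 16 vesicle diameters geometrically spaced
130–473 nm, six crystal sizes (0.2–0.7 of the diameter, capped by
geometry), six maturation steps and six cytoplasm concentrations linearly
spaced 0.06–0.2 g ml⁻¹ — 3,456 entries; the per-axis schedules beyond the
stated ranges are our interpolation choices.

## X-ray physics

Elemental mass attenuation coefficients come from bundled water-window
photoabsorption factors f₂ (H, C, N, O, P, S, Zn; 450–540 eV, log-log
interpolated), compiled from the standard Henke–Gullikson–Davis
tabulation; the dominant carbon and oxygen entries are pinned by
cross-checking the composite values this package must reproduce — water
1,114.279 cm⁻¹ and DOPC 9,264.835 cm⁻¹ at 517 eV — to within 0.01%. The
average protein composition (H:C:N:O:S = 0.498:0.320:0.085:0.095:0.002 by
atom count) gives a protein MAC of 7,971 cm² g⁻¹, i.e. 0.97 µm⁻¹ at
crystal-interior density. Voxelisation splats bead masses trilinearly,
tracks per-ingredient MAC, lets water fill the non-solute volume, and
conserves deposited mass to 0.1% by construction (an error is raised
otherwise).

A consequence worth stating: with these constants a 0.2 g ml⁻¹ protein
solution has LAC 0.253 µm⁻¹. An LAC of 0.35 µm⁻¹ — the value measured in
beta-cell cytoplasm — corresponds to 0.34 g ml⁻¹ of protein, and no
protein composition can reach 0.35 µm⁻¹ at 0.2 g ml⁻¹ at 517 eV, since
that would need a MAC above even pure carbon's. The idealised-vesicle
scenarios therefore fix the surrounding cytoplasm by its LAC
(0.35 µm⁻¹), not by the 0.2 g ml⁻¹ concentration.

The imaging chain: parallel-beam line integrals about the y axis over
180° (181 angles — adequate sampling for the 181-voxel embedding width;
both configurable); Gaussian PSF of 60 nm FWHM on the projections
(matching the instruments' 50–60 nm resolution); Poisson shot noise at
5,000 photons/pixel incident (a typical water-window exposure; the paper
states neither); per-projection uniform ±0.5-voxel registration jitter
applied as an exact Fourier translation (interpolated shifts add spurious
blur); Ram-Lak filtered back-projection per slice; 10-replicate
averaging. The simulated sample is cylindrical (zero outside the inscribed
circle), as the parallel-beam transform requires. The embedding volume is
181×17×181 voxels (6.8 µm × 0.64 µm × 6.8 µm) — the 17-voxel thickness of
the library protocol with a reduced in-plane width; quantities are
measured near the centre, far from the boundary.

Radial profiles are means over one-voxel annuli of the central slice
through the blob, centred on the brightest pixel (first-index tie-break).
For classification the centre search runs on a lightly smoothed slice and
profiles average the three central slices; for peak measurements the raw
brightest-pixel convention is kept. The membrane contribution is measured
on paired builds (shared seed, identical protein placements, lipids
toggled) as the membrane's share of the blob-integrated absorbance above
water within the vesicle footprint — the quantity that reflects the
membrane's ~15–20% share of the feature's dry mass; a naive peak-value
ratio is also available but reads only the 10 nm of bilayer crossing the
central line of sight and lands at 0–3%.

## Detection and classification

Blobs are maxima of the scale-normalised (−σ²∇²G) response over space and
16 scales (radii 60–261 nm), with the field mean removed so the truncated
kernel's DC leakage cannot respond to flat regions; sphere-overlap
(IoU > 0.3) suppression keeps the stronger detection; the reported radius
is σ√3 (exact for solid spheres; σ√2 for Gaussian blobs). The detection
threshold maximises accuracy on a labelled set — in the synthetic protocol,
30 planted mature granules of varied size against 30 faint diffuse decoy
bumps — with ties resolved towards the higher threshold; when classes are
separable this puts the threshold at the weakest genuine feature, which is
why immature vesicles (≈13% contrast over cytoplasm, versus ≈100% for
crystals) fall below it and go undetected, reproducing the published
asymmetry.

Library profiles are generated by passing analytic concentric-shell
phantoms through the same projection/FBP operator noise-free, plus the
expected blur of the averaged jitter; replicate-averaged noisy
reconstructions converge to this reference because the chain is linear in
the line integrals. (A PSF-only library is measurably sharper than
reconstructed data and systematically dragged best fits one maturation
step down.) Fitting maximises R² over the first six radial bins
(≈225 nm, the vesicle), breaking ties with the 15-bin score that includes
surrounding cytoplasm; maturity classes are step 1 = immature,
steps 2–5 = transitional, step 6 = mature. A constant experimental profile
has undefined R² and is reported per-blob as a degenerate case.

## What the synthetic studies show — and don't

The generators emulate the *structure* of the real inputs: keyword
enrichment by odds ratios, proteome membership rates, abundance
log-normality, and granules as ideal concentric spheres in homogeneous
cytoplasm. They do not emulate annotation vocabulary correlations, real
isolation impurity profiles, aspherical or docked granules, cytoplasmic
texture (organelles, ribosomes), the capillary or missing-wedge artefacts.
Passing tests therefore demonstrate internal consistency of the method and
recovery of planted truth under the stated noise model, not performance on
experimental maps.

Planted-phantom classification recovers 8 of 9 (size × maturation) plants
at the suite seed and 7–8 of 9 across seeds; every confusion observed is
between adjacent maturation steps whose physical contrast is marginal
(steps 1 and 2 differ by 0.006 µm⁻¹ of lumen LAC), i.e. the class
boundaries, not the fitting machinery, set the error floor. The simulated
mature-vesicle peak comes out at ≈0.67 µm⁻¹ — the blurred crystal LAC of
0.70 µm⁻¹ — higher than the published 0.538 µm⁻¹, which is not reachable
from these material constants under any slice-profile convention; the
immature peak (≈0.44–0.46 µm⁻¹) and the detection contour diameter
(≈178 nm) match the published values closely.

## Numerical conventions

Lengths are nm in model space, Å in structure space, µm⁻¹ for LAC.
Rounding of copy numbers is half-to-even; maturation partitions use
largest-remainder rounding so counts sum exactly. All randomness flows
from one master seed through named, independently spawned PCG64 streams
(catalog, packing, tomogram, detection, …), so any stage can be re-run in
isolation and the full build is reproducible bit-for-bit. K-means bead
models use seeded k-means++; k = 1 reduces to the unweighted coordinate
centroid, and bead mass shares always sum to the exact molecular weight.
MRC maps are written as mode-2 CCP4-compatible volumes with the voxel size
in the cell header.
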