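# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package, in the order of the processing pipeline.

## GLI images

The Grey Level Index of a measuring field is the fraction of its pixels
strictly darker than a gray threshold. Defaults follow the conventional
acquisition geometry: 17 μm nominal field edge at 1.02 μm/px, giving an
effective field of 17 px = 17.34 μm; both nominal and effective sizes are
recorded in metadata. The threshold, when not supplied, maximizes the
between-class variance of the gray histogram (Otsu's criterion) — the
literature says only that the threshold is derived "from the histogram",
so the exact rule is a package decision, as is the tie convention
("darker than" is strict `<`; a pixel equal to the threshold counts as
background). Trailing partial fields are dropped rather than padded, so no
field mixes tissue with out-of-image area. A constant image has no
separable classes and raises.

GLI is invariant under any strictly monotone gray remapping that preserves
each pixel's side of the threshold, and the mean over all fields equals
the global dark-pixel fraction of the covered region; both are tested.

## Traverses and profiles

Traverses connect the outer (layer I/II) to the inner (layer VI/WM)
contour. The default construction pairs equidistant arc-length positions
on the two contours with straight segments — exact for parallel plates and
concentric arcs; an optional Laplace mode solves ∇²φ = 0 between the
contours (Dirichlet 0/1 on the contours, Neumann at the ribbon's open
ends) and follows ∇φ, which is preferable for strongly curved ribbons.
Profiles are sampled by bilinear interpolation of the GLI grid at
`n_depth = 100` equidistant arc-length positions; 100 is the conventional
sampling density for this method family and is configurable. Cortical
thickness in μm is recorded per traverse.

## The 10-element feature vector

A profile y over depths x ∈ [0, 1] is treated as a weight distribution
p_i = y_i / Σy: the descriptor is (ȳ, cog, sd, skew, kurt) with
cog = Σ p_i x_i and central moments about it, followed by the same five
statistics of the absolute central-difference derivative |dy/dx| (computed
with scalar spacing 1/(n−1), so a constant profile has an exactly zero
derivative block, defined as five zeros rather than NaN). Zero depth
spread sets skew = kurt = 0; an all-zero profile has undefined weights and
raises. The historical description of the descriptor ("centre of gravity
in x- and y-direction") over-counts a 10-element vector; here one
amplitude-weighted cog per block is used, with ȳ as the amplitude-level
summary — an interpretation, recorded as such. The shape features are
invariant under positive scaling of the profile (weights normalize); ȳ
scales linearly; both are property-tested.

## Border detection

For block size b and position i, the left block covers profiles [i−b, i)
and the right [i, i+b) (blocks abut the candidate position). Block means
and pooled within-block covariances come from cumulative first and second
moments, so a whole MD row is one batched 10×10 solve. Significance uses
Hotelling's T² = (b²/2b)·D² referenced through
F = T²(n−p−1)/(p(n−2)) to F(p, n−p−1), n = 2b, p = 10; Bonferroni divides
α by the number of admissible positions of that block size (each block
size is one test family; the cross-block-size voting supplies the second
level of control, and edge positions without two full blocks are excluded
from the count).

Covariance handling: with the smallest block (b = 12) the pooled degrees
of freedom (22) still exceed the 10 features, so the *unregularized*
pooled covariance is the default — this keeps the T²→F reference exact,
which the calibration tests confirm (type-I rate 0.052 at α = 0.05 under
the null). Analytic OAS shrinkage toward a scaled identity is available
via config but deliberately not the default: the 10 features live on very
different scales, and shrinking toward tr(S)/p·I inflates the
small-variance directions enough to mask real laminar contrasts. A
singular covariance (e.g. identical profiles) falls back to the
pseudo-inverse, which yields D² = 0 whenever the mean difference vanishes.

Decision rule: per block size, strict local maxima of the MD curve
(plateaus take the leftmost index) that survive correction are candidate
maxima; maxima within half a block size of a stronger one are suppressed,
since a single transition produces one MD ridge roughly a window wide on
which noise carves secondary peaks. A position collects one vote from each
block size with a surviving maximum within ±2 profiles; positions with
votes from ≥ 50% of the block sizes are accepted, and accepted positions
within ±2 of each other merge into one border. Vote ties break by the mean
MD across block sizes — a mirror-symmetric rule chosen so border positions
are equivariant under reversing the sequence (a left/rightmost rule is
not) — then by the leftmost index. The vote fraction, tolerance and
Bonferroni scope quantify a qualitative criterion ("a significant maximum
at different block sizes"); none of these numbers is prescribed by the
method's literature, all are configurable, and all are echoed in every
result.

## Synthetic histology

Laminar templates are piecewise-constant layer means convolved with a
Gaussian of scale `transition_width` (computed in closed form from normal
CDFs, with the outermost layers extended to ±∞, so values never leave the
[min, max] of the layer means). The six-layer presets differ chiefly in
layer IV prominence and infragranular density — the kind of contrast that
separates neighbouring areas. Profile noise is i.i.d. Gaussian *truncated*
(not clipped) to [0, 1]; truncation biases moments near the bounds, which
the moment tests account for by staying away from the extremes. The noise
scale is a free parameter (real staining noise is not characterized by the
method's literature); the planted-border study conditions use
noise_sd = 0.05 on a laminar contrast of ~0.25 GLI, and the null/type-I
sweep covers noise_sd 0.01–0.10.

Rendered sections place cells as dark disks of an inhomogeneous Poisson
process with intensity g(depth)/(π r²) inside an annulus-sector ribbon, so
the expected covered fraction of a field at depth x is 1 − exp(−g(x)) — a
Boolean-model vacancy law that the GLI stage is tested against. At these
densities a 17 μm field contains roughly one cell, so raw GLI values are
very noisy; the image-mode pipeline therefore smooths the GLI grid with a
3-field boxcar (~52 μm, small against layer thicknesses) and the demo
geometry keeps traverses ~60 μm apart so the smoothing never correlates
neighbouring profiles — the independence the block statistics assume.

Subject label volumes displace each canonical area mask by an independent
integer translation (max-norm ≤ jitter); colliding translations are
redrawn so areas stay disjoint, and a translation that would push a mask
off-grid raises (leave a margin of at least the jitter). Volume tables
draw fresh weight ~ N(1250 g, 120 g) and a true shrinkage ~ N(2.0, 0.15)
(paraffin embedding roughly halves tissue volume), both truncated to
physical ranges, with per-area volumes from the stated group normal models
truncated positive.

The planted two-family clustering scenario jitters layer GLI values by
0.01 within a family against a 0.33 layer-IV contrast between families.
Moment features amplify layer jitter strongly (a 0.02 layer jitter already
produces derivative-skew spread comparable to the family contrast), so
0.01 is the regime an unambiguous twofold dendrogram split represents;
larger within-family variation genuinely blurs the structure, which is a
property of the descriptor, not of the clustering.

What the generators do *not* emulate: neuron morphology and size
distributions, staining gradients and artifacts, section tears, curvature-
and obliquity-induced profile distortions, and 3D tissue continuity.
Passing tests therefore demonstrate the statistical machinery under its
own assumptions, not robustness to those real-data effects.

## Area statistics

Inter-area distances are Euclidean between per-area mean feature vectors
after z-scoring the pooled profiles (the features' scales differ by orders
of magnitude; a flag disables standardization). Agglomeration is Ward's
linkage via scipy; merge heights are monotone by construction and the
dendrogram exports to Newick. Clustering per-area means follows the
"distance between given areas" reading of the method; clustering
individual profiles instead is possible by constructing one sample per
profile group.

The shrinkage factor is F = (fresh weight / ρ) / processed volume with
ρ = 1.033. The source literature prints the density as g/mm³, which is
dimensionally implausible for brain tissue; it is treated as g/cm³ here
(so weight in g and volumes in cm³ are consistent). Cavalieri volumes are
F · section spacing · Σ section areas, spacing in μm converted to mm.

The permutation contrast test re-assigns group labels `n_iter` times
(vectorized via random orderings), uses the add-one correction
p = (1 + #{|null| ≥ |obs|}) / (n_iter + 1) so p is never exactly zero, and
is two-sided by default (whether the original rule was one- or two-sided
is not stated; `alternative="greater"` gives the one-sided variant, and
the rule used is part of every result). The default 10,000 iterations is a
screening scale — the convention for final inference in this method family
is 1,000,000, available by argument; type-I calibration at the default is
verified to lie in [0.035, 0.065] at α = 0.05.

## Population maps

Probability maps count, per voxel, the subjects whose label volume carries
the area — exact multiples of 1/n by construction. The maximum probability
map assigns each voxel the argmax label; the 40% inclusion threshold
applies only where an area borders unmapped cortex, operationalized as
voxels where no *second* mapped area has nonzero probability (the order —
argmax first, threshold second — is a documented choice). Argmax ties are
resolved by the higher mean probability over the 26-neighborhood
(zero-padded at faces), remaining ties by the lowest area id, and every
fallback is counted in the result and logged. Maps live in voxel space
with an affine to world coordinates; no resampling or smoothing is applied
and no claim of registration to any reference template is made.

## Problem sizes

The test-suite and acceptance-script simulations use: 200 null sequences
(10 noise levels × 20 seeds) and 50 + 10 recovery sequences of 120
profiles for the border detector; 2,000 replicates for Hotelling
calibration; 1,000 replicate permutation tests of 10,000 iterations; 100
seeds for cluster recovery; and one end-to-end rendered-image run per
seed. These sizes give Monte-Carlo standard errors comfortably below the
acceptance margins while keeping a full run around half a minute.

## Known limitations

- Border detection treats profiles as independent; obliquely cut or
  strongly curved regions violate this and must be excluded by the caller.
- The Hotelling reference is exact only for the unregularized covariance;
  enabling shrinkage makes p-values approximate.
- The feature descriptor is sensitive to overall staining level through ȳ
  and the derivative mean; section-to-section staining differences should
  be handled before pooling across sections.
- 2D borders only: closing borders across serial sections into surfaces is
  out of scope, as are nonlinear registration and any atlas-space claims.
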