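# Methods

This note documents the models, numerical choices and known limitations of
`hepavessel`, in the order the pipeline applies them.

## Conventions

Volumes are scalar grids with axis order (x, y, z), z being the slice
axis; all "per-slice" operations iterate over z. Voxel indexing is
0-based and a voxel's physical position is the position of its center, so
distances (ASSD, Hausdorff) are unambiguous. Spacing is carried in mm;
NIfTI files are written as NIfTI-2, whose header stores voxel sizes in
double precision, so anisotropic clinical spacings such as
(0.684, 0.684, 2.75) mm round-trip exactly.

## De-biasing

MRI coil and field nonuniformity multiplies the image by a smooth "bias"
field. The corrector models the bias as the exponential of a polynomial of
total degree 3 in the three (scaled) coordinates, fitted by least squares
to the log intensity and divided out; the geometric mean over the fit
support is preserved. The fit support is the organ mask when one is
supplied, otherwise all nonzero voxels — restricting the support matters,
because background intensity levels otherwise leak across the organ border
into the estimate and the divided-out field imprints artificial gradients
(on the synthetic liver these raised the interior vesselness response from
0.004 to 0.18 of the maximum).

A least-squares fit is a projection, so de-biasing is exactly idempotent,
and a degree-3 field cannot absorb vessel-scale structure, so local
intensity ordering is preserved. An earlier candidate — dividing out a
¼-field-of-view Gaussian smoothing of the log intensity — was rejected:
smoothing is not a projection (a second pass kept changing voxels by up to
2.5%) and its estimate follows anatomy near organ borders. Any corrector
honoring the same contract (homogenize intensities, preserve local
ordering, idempotent to ~1%) can be substituted. Degree 3 suffices for
single-lobe synthetic bias fields and typical coil profiles; a strongly
multi-lobed field would need a higher degree.

## Resampling

Vesselness needs isotropic voxels; images are resampled to the finest
in-plane spacing (upsampling z) with a separable Lanczos windowed-sinc
kernel of radius 4 samples. Kernel rows are normalized to sum to one, so
constants — and hence the volume-wide mean of a constant image — are
reproduced exactly; edges use sample replication; the output grid is the
set of new-spacing samples that fit within the input's voxel-center
extent, and the inverse resampling accepts an explicit target shape so
the original grid is reproduced bit-for-bit in size. Masks are resampled
with linear interpolation and re-binarized at 0.5: a sinc kernel on a
binary field rings, and ringing in a mask becomes spurious islands.

## Vesselness filter

At each scale σ (in voxels of the isotropic grid) the image is convolved
with scale-normalized Gaussian second-derivative kernels (multiplied by
σ², required for cross-scale comparability of the multiscale maximum).
The truncated discrete second-derivative kernel has a slightly nonzero
sum; its constant response is subtracted so flat regions yield exactly
zero eigenvalues. Per-voxel eigenvalues come from the LAPACK symmetric
solver and are sorted by absolute value with ties broken by signed value
ascending — a deterministic ordering.

The response combines the plate discriminator Ra = |λ₂|/|λ₃|, the blob
discriminator Rb = |λ₁|/√(|λ₂λ₃|) and the structure norm S with
α = 0.3 and β = 0.7, and is zeroed where λ₂ > 0 or λ₃ > 0 (bright
structures; dark vessels are handled by negating the input, which flips
every eigenvalue sign and is exactly equivalent to negating the
condition — the two routes are property-tested against each other). The
distinguishing feature of this variant is the structure term
1 − exp(−S²/c) with the contrast constant *c* used as-is in the
denominator (not 2c²), and c set per volume and per scale to half the
maximum Frobenius norm of the Hessian over the (optionally masked)
volume. At the strongest voxel S = 2c, so the term saturates and the
response of any structure above a few percent of the volume's maximum
contrast approaches 1 — weak vessels are enhanced aggressively. The
flip side, quantified below, is that image noise also acquires a
low-but-nonzero response "skirt".

**Scale selection.** σ is the one parameter that must be chosen for the
structure size of interest: a cylinder of radius r responds most strongly
near σ ≈ r/√2 and scales well beyond r only widen the spatial support of
the response (by roughly σ) without improving detection.
`scales_for_radius(r_px)` builds the list [1, r] in steps of 0.5
accordingly. The package default, σ from 1 to 12 in steps of 0.5, targets
clinical hepatic trees whose vessels span ~3–20 mm diameter at ~1 mm
isotropic voxels. For the desk-scale experiments here — tube phantoms and
a ~70 mm synthetic liver with vessels up to 6 mm — scales are matched to
the largest vessel radius in voxels; on such small volumes σ = 12 is
organ-scale, and the multiscale maximum would flood the basic vessel
model (measured: 40% of liver voxels above the 0.05 cut).

## Automatic thresholding

Both selectors operate on the full 2¹⁶-bin histogram after one global
affine rescale per volume from [min, max] to [0, 65535] (fixed before any
slicewise work, so per-slice thresholds share one intensity axis). The
variance criterion maximizes w₀w₁(μ₀−μ₁)²; the entropy criterion
maximizes the sum of Shannon entropies of the two normalized class
distributions (natural log; 0·log 0 = 0). Both return the smallest
optimal threshold on ties and are invariant to scaling counts; both are
verified against exhaustive-search oracles on random histograms. The
vessel side of a threshold depends on the input: below-threshold for
de-biased anatomical images (vessels hypointense), above-threshold for
vesselness maps.

## Pipeline details

* 2D connectivity is 8-connected (diagonally touching vessel cross
  sections stay one object); the region-growing neighborhood is the full
  3D 27-neighborhood.
* Small-object removal is per-slice component-area filtering with cutoff
  ⌈π(d/2)²/(dx·dy)⌉ for d = 3 mm (≥ keeps an object exactly at the
  cutoff). Area filtering rather than a literal morphological opening
  preserves thin-but-long objects that meet the area criterion.
* Discrete discs (ROI dilation radius 5 px, mask erosion radius 6 px)
  contain the pixels whose center distance is ≤ r; these radii are pixel
  counts, not mm, with config overrides.
* Local thresholding unions the dark-side decisions of all (possibly
  overlapping) ROIs; ROIs with degenerate single-bin histograms contribute
  nothing.
* Region growing recomputes per-slice medians after each completed
  wavefront; a candidate needs a marked 26-neighbor and intensity at or
  below (dark mode) the median of the already-marked voxels in its own
  slice. Growth is restricted to the liver mask: the masked image is zero
  outside the organ, and zero trivially satisfies the dark-side criterion,
  so unrestricted growth would flood the background. Growth is monotone
  and terminates; the implementation is tested against a direct
  brute-force re-implementation on toy volumes.
* Every intermediate (O1–O16) is retrievable for inspection and can be
  written to disk by the CLI.

## Synthetic data

**Tube phantoms** emulate a fluid-filled tube embedded in gel: tube
diameters 4/6/8 mm, in-plane resolutions 1.56 and 1.04 mm, 2 mm slices —
2.56 to 7.69 pixels per diameter — perpendicular to the slice plane or
tilted within the x–z plane. Per-voxel tube coverage is computed by
supersampled rasterization of the cylinder (16 subdivisions per axis;
only voxels straddling the surface are supersampled), keeping per-slice
coverage sums within 0.5% of the analytic cross-section area. Intensity
is gel + (tube − gel)·coverage with gel 200, tube 100 (vessels dark, as
in hepatobiliary-phase imaging), additive Gaussian noise of sd 2 (2% of
the tube–gel contrast) and an optional multiplicative bias field. The
tube axis passes through an in-plane pixel corner, realizing the
corner-centered placement of the reference-area model. Gaussian rather
than Rician noise is appropriate at this SNR (≈100 on the gel);
the glass tube wall is not modeled separately — the outer diameter is
treated as the fluid diameter.

**Synthetic livers** are ellipsoidal bright-parenchyma regions (the mask
is an input downstream, as in clinical use) containing darker vessel
capsules with a one-voxel linear partial-volume ramp, surrounded by a
darker background, with noise and bias as above. The default tree runs
predominantly along z — the orientation in which per-slice cross sections
are compact — with a 6 mm main vessel, a 4 mm branch and a separate 2 mm
twig below the pipeline's 3 mm criterion. The bias field is a product of
per-axis 1 + a·cos(πu) factors with a chosen so the corner-to-corner
deviation equals the requested amplitude (default 0.2); unlike a plain
cosine product it keeps a substantial swing across the organ.

What the generators do *not* emulate: vessel curvature and caliber
tapering, real parenchymal texture and lesions, flow and motion
artifacts, Rician noise at low SNR, k-space acquisition effects, and
inaccurate liver masks. Passing phantom tests therefore demonstrates the
method's geometric and contrast behavior under idealized conditions, not
clinical-grade performance.

## Evaluation machinery

The **reference-area model** handles the partial volume effect: a circle
of the given pixels-per-diameter is placed on the unit grid centered on a
pixel corner, an edge midpoint, and a pixel center; per-pixel coverage is
computed by midpoint supersampling (64× per axis; total coverage within
0.1% of πr²). The *optimal* area is the ≥50%-coverage count minimized
over placements, the *maximum* area the >0 count maximized over
placements, the *calculated* area πr². A segmented per-slice area inside
[optimal, maximum] is a valid segmentation; otherwise the pixel count
outside the band divided by the calculated area is the relative area
error (%), and per-phantom scores are medians over interior slices (the
two slices at each end, where the tube enters and leaves, are excluded).
Tilted tubes are scored against the same per-resolution circle bands as
perpendicular ones, mirroring the original evaluation design. The
geometrically refined alternative — the band of the elliptical
cross-section d/cosθ × d, including a continuous-offset sweep
(`tilted_tube_reference`, `circle_coverage(..., offset=...)`) — is also
provided; under the ellipse band, variance thresholding of tilted
vesselness maps shows a genuine 5–13% median undersegmentation at the
three highest resolutions that the circle band absorbs.

Object-level metrics work on per-slice 2D connected components: a
reference object is *detected* if at least one segmented pixel overlaps it
(hit rate = detected fraction); per-object sensitivity is |seg∩ref|/|ref|;
ASSD and Hausdorff distances are computed between border-pixel centers
(4-neighborhood complement test), in px and mm (in-plane spacing), via
k-d trees and verified against O(N²) brute force. Image-level values are
medians over detected objects — robust to the skewed error distributions
segmentation produces. ROC curves sweep up to 1024 quantile-spaced
thresholds descending, predicted-positive = score ≥ threshold.

## Behavior of the thresholding baselines (what the experiments show)

With slice-level **variance minimization**, both the de-biased originals
and the radius-matched vesselness maps of the tube phantoms segment with
0% median area error at all five resolutions, perpendicular and tilted —
the high-contrast bimodal histograms put the Otsu threshold in the gap
between modes.

Slice-level **entropy maximization** on the original images oversegments
severely: with a small foreground, the entropy balance pushes the
threshold deep into the gel intensity distribution, marking a roughly
constant *fraction* of gel pixels. Because that fraction and the
calculated area both scale with resolution⁻², the relative error depends
essentially on the tube diameter in mm; it therefore falls strictly with
pixels/diameter within each in-plane resolution (4→6→8 mm tubes) and
shows a decreasing overall rank trend across all five points, but is not
strictly monotone across the 1.56→1.04 mm boundary (where an 8 mm tube is
followed by a 6 mm one).

On **vesselness maps**, the entropy criterion locks onto the noise
response skirt described above (threshold ≈ 0.007 of the maximum) and
oversegments by orders of magnitude — median errors of order 10³ % — at
every noise level tested, including the noise-free limit, where sinc
resampling ripple plays the same role. This is a property of the
entropy criterion applied to a histogram with a heavy low-value tail,
not an implementation artifact (the selector is oracle-verified); it is
the package's one deliberate departure from the expected qualitative
behavior of the entropy baseline on filtered images, and the
corresponding acceptance check is left failing rather than adjusted.

## Problem sizes

The shipped experiments run on one CPU in minutes: phantom volumes are
31–70 px in-plane × 20 slices (48 mm field of view perpendicular, 72 mm
tilted to keep the leaning tube inside), and the synthetic liver is
64×64×28 at (1.2, 1.2, 2.4) mm — about ⅖ clinical scale, with vesselness
scales matched to its vessels as described under scale selection. All
randomness flows from explicit integer seeds through numpy's
SeedSequence; identical seeds give bit-identical volumes and masks.

## Known limitations

* Clinical-image performance (hit rates, sensitivities, surface distances
  on patient data) is out of reach of synthetic validation and is not
  claimed; the object-level machinery is provided for users with their own
  reference segmentations.
* The pixel-unit parameters (ROI radius 5 px, erosion radius 6 px) do not
  scale with resolution; at resolutions far from ~1 mm they should be
  overridden.
* The region-growing threshold (slice median of marked voxels) assumes
  vessels darker than parenchyma; bright-vessel protocols use
  `dark_vessels: false`, which flips every polarity contract.
* Liver masks are trusted inputs; mask errors propagate (the erosion step
  only suppresses a border band, per its design).
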