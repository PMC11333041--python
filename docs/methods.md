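# Methods

## The measurement problem

A club ending (CE) is a single auditory afferent terminal whose oval contact
on the Mauthner-cell lateral dendrite bounds one synapse anatomically.
Protein-retention expansion microscopy enlarges the specimen ~3.9× linearly,
so structures that are diffraction-confounded in situ — individual
gap-junction (GJ) plaques, the interleaved adherens-junction (AJ) mesh,
peripheral glutamate-receptor (GluR2) zones, and the axial stagger of pre-
vs. postsynaptic proteins — become measurable with a confocal microscope.
`cemap` implements the measurements this enables: contact morphometry and
expansion isotropy, puncta counting/sizing and connexon estimation,
thresholded Manders colocalization, center/periphery fluorescence (CTCF),
labeling occupancy, and line-scan peak offsets. All lengths are carried in
µm on the image (expanded) scale; biological quantities are obtained by
dividing by the expansion factor at measurement time, never stored.

## Synthetic scenes: what they emulate

Because raw CE stacks are not distributed, every stage is validated against
a generator whose defaults are calibrated to the study conditions:

- **Contact geometry.** Long and short pre-expansion diameters are drawn
  independently, L ~ N(2.11, 0.228) µm and S ~ N(1.62, 0.160) µm (SDs are
  the reported SEMs × √38), truncated to S ≤ L. Drawing L and S/L
  independently instead would give a contact-area spread roughly twice the
  reported one, which is why the package samples the diameters. The contact
  surface is a paraboloid cap with rim height (concavity) 0.26 µm pre- /
  ~1 µm post-expansion; 0 gives a flat 'en face' contact.
- **GJ puncta.** Count ~ round(N(36.73, 4.27)), truncated at ≥ 5 (SD from
  the reported SEM 1.287 × √11). Post-expansion areas follow a log-normal
  clipped to the observed 0.06–1.99 µm² range, with mean 0.378 µm² — fixed
  by the reported totals (≈12,425 connexons per contact at
  12,000 connexons/µm² and a 13.4× areal factor over 36.73 puncta) — and
  the lower 0.5 % quantile pinned at the smallest observed punctum. Disks
  are placed by rejection sampling, largest first, pairwise edge gaps
  ≥ 0.05 µm (post scale), fully inside the contact. When a drawn puncta set
  cannot pack (effective disk fraction > 0.48, near the jamming limit of
  random sequential placement), the *contact* is redrawn rather than the
  count, so the count distribution — the quantity the recovery experiments
  consume — stays unbiased; the contact-size mean shifts up ~3 %, which no
  downstream comparison uses. A genuinely over-dense configuration raises
  `PlacementError`.
- **GluR2 and bare membrane.** 8–12 GluR2 patches (radius 0.7–1.05 µm post)
  with centroids area-uniform in the peripheral quarter annulus
  (elliptical radius ρ > √0.75), plus 10–16 unlabeled bare-membrane patches
  (radius 0.3–0.52 µm) anywhere in the contact. The AJ region is the
  complement: contact minus GJ, GluR2 and bare patches, so the four masks
  partition the contact exactly and ground-truth occupancies sum to 1 by
  construction. AJ abuts GJ directly (zero-width boundary): modeling the
  unlabeled remainder as discrete patches rather than thin guard rings
  around every punctum keeps it resolvable at the instrument PSF and
  reproduces the patchy unlabeled regions seen in real occupancy maps.
  Mean ground-truth occupancies land at ≈ GJ 33 %, AJ 40 %, GluR2 20 %,
  unlabeled 7 % (reported: 34.8 / 38.1 / 18.9 / 8.1 %).
- **Expansion.** Linear factor k (default 3.9) along the long axis, k·r
  along the short axis (anisotropy r, default 1); disk radii scale by k√r,
  heights by k. With r = 1 every area scales by exactly k².
- **Imaging.** Anisotropic Gaussian PSF with lateral FWHM 0.28 µm and axial
  FWHM 0.49 µm (midpoints of the instrument's stated resolution ranges,
  divided by 2.355 for sigmas); pixel 0.05 µm, z-step 0.25 µm; label masks
  deposited trilinearly at their surface height (nearest-voxel deposition
  would quantize sub-pixel offsets away), postsynaptic markers displaced
  along the local surface normal (Cx34.1 by 0.03 µm, ZO1 by 0.21 µm, both
  treated as image-scale distances); readout
  Poisson(500 × blurred density + 10) + N(0, 3), clipped at 0. Side views
  put the camera along the short axis so normal offsets of a flat contact
  fall in the image plane — the configuration used for line-scan
  experiments. A fluorophore-assignment map with per-fluorophore chromatic
  displacements (default 0) makes the secondary-antibody swap control an
  executable experiment.

What the generator does **not** emulate: vectorial/asymmetric PSFs,
refractive-index mismatch, local gel distortion beyond the global
anisotropy knob, labeling stochasticity (epitope density is uniform on each
structure), and autofluorescent clutter outside the contact. Passing
recovery tests therefore demonstrate correctness of the measurement code
under idealized optics, not robustness to every artifact of real tissue.

## Numerical and design choices

- **Contact outline.** Threshold (Otsu by default), morphological closing
  (0.8 µm works well when the contact is labeled by discrete puncta — large
  enough to bridge inter-punctum voids, small enough not to distort the
  outline), hole filling, largest component, second-moment ellipse fit.
  Ellipse-fit diameters, not Feret calipers: reproducible on concave
  outlines; border-touching components are flagged. On puncta-defined
  outlines the fitted diameters run ~10 % short of the generating ellipse
  because labeling stops inside the geometric rim; ratio statistics (S/L,
  expansion factors) are unaffected.
- **Puncta splitting.** Merged puncta are separated by a watershed whose
  markers are h-maxima of the lightly smoothed image with prominence
  0.03 × the in-ROI dynamic range — deep enough that shot noise on a
  punctum plateau (≲ 1 % after smoothing) never seeds a marker, shallow
  enough to keep the ~17 % valley between disks separated by the default
  edge gap. Shape-based (distance-transform) markers were tried and
  rejected: once the thresholded gap between neighbours closes, the
  component's neck is too wide for a geometric split. Residual merging
  biases detected counts ≈ −2 % at calibrated density; splitting can be
  disabled (`split_touching=False`) to reproduce the plain
  connected-component behaviour and its larger undercount.
- **Minimum punctum area** 0.05 µm², just below the smallest reported
  plaque, rejects noise speckle without clipping the real size range.
- **Projections.** Maximum projection for display-like images and
  segmentation; *sum* projection for integrated-intensity measurements
  (occupancy, CTCF): the summed column intensity of a blurred surface is
  invariant to how the surface tilts through the z slices, whereas the
  per-slice maximum dims with tilt and z-phase.
- **Occupancy.** Default per-channel Otsu within the ROI. In exclusive
  mode, contested pixels go to the channel with the larger
  plateau-normalized intensity (intensity / robust in-ROI maximum): for two
  abutting blurred structures the crossover of the plateau-normalized edge
  profiles falls exactly on their shared boundary, while normalizing by the
  thresholds (which may sit at different fractions of each channel's
  plateau) would shift the assignment boundary by up to ~0.03 of the
  contact area. Noiseless recovery of all four ground-truth fractions is
  within 0.03.
- **Manders.** Thresholded coefficients with recorded thresholds; raw
  coefficients via manual (0, 0). Undefined results (zero denominator) are
  excluded from batch means with a flag — silent zeros would bias averages
  downward. Costes' regression search walks the candidate threshold down
  until the below-threshold pixels decorrelate.
- **Center/periphery.** The center ROI is the set of contact pixels whose
  normalized elliptical radius (from the mask's own second moments) is
  ≤ √0.75; center and periphery partition the contact pixel set exactly and
  the center holds 75 ± 1 % of the pixels on rasterized ellipses. Lateral
  views are rejected — the partition is defined en face only.
- **Peak localization.** Gaussian fit over ±0.18 µm (≈ ±1.5 × lateral FWHM
  after accounting for the sampling step) around the discrete maximum,
  3-point parabolic interpolation as fallback, boundary maxima flagged and
  excluded from statistics. Offsets are signed along the line (positive =
  channel B farther from the line start); group statistics use magnitudes.
  Offsets far below the PSF FWHM are recovered without bias — localization
  precision, not resolution, limits the measurement — which is how the
  0.03 µm connexin–connexin separation is measurable at a 0.28 µm FWHM.
- **Statistics.** Two-sided two-sample t-tests (scipy), one-way ANOVA with
  Tukey HSD (statsmodels); S/L group statistics are means of per-contact
  ratios, expansion factors are ratios of group means — the two conventions
  the printed values imply.
- **Connexon arithmetic.** `round(area / areal_factor × density)` with the
  areal factor exposed as a parameter. The printed derived values are
  mutually inconsistent at the percent level (1.99 µm² / 13.4 × 12,000
  ≈ 1782 vs. a printed 1775; the corrected-area range printed as
  4–148 nm² is off by 10³ from 0.004–0.148 µm²); the package documents
  rather than reverse-engineers the exact factor used.

## Problem sizes

Recovery experiments run at the sizes the reported statistics imply: 50
en-face scenes for puncta-count recovery, 30 and 37 side-view line scans
for the connexin–ZO1 and connexin–connexin offsets, 100–250 replicates for
Monte-Carlo power and bias checks. The full test suite and the acceptance
script each complete in well under a minute of compute on one core.

## Known limitations

- Detected puncta counts carry a small negative bias from PSF merging (the
  same caveat the source method reports); the bias grows quickly if the
  edge-gap parameter is reduced below the default.
- The contact outline from puncta-defined labeling underestimates absolute
  diameters (~10 %); use filled-label channels or ground-truth masks when
  absolute size matters.
- The exclusive-occupancy boundary assignment assumes comparable labeling
  plateaus within each channel; strongly non-uniform labeling would move
  the crossover.
- The Costes threshold search uses a fixed 256-step scan, adequate for
  8–16-bit data but coarse for float images with extreme dynamic range.
- 3D (volumetric) punctum measurement, radial profiles, and per-punctum
  center/periphery classification are out of scope.
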