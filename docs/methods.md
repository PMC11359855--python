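# Methods

## Quantification procedure

A capture is scored in five deterministic steps.

**Grayscale.** RGB captures are reduced with Rec. 601 luma weights
(0.299, 0.587, 0.114) and half-up rounding; these weights are the de
facto default for this conversion and are adopted because acquisition
software rarely documents its own. 16-bit exports are mapped linearly
onto [0, 255] (full-range rescale, chosen over bit-shifting so both
endpoints are exact).

**Inverse-binary threshold.** Foreground = pixels with intensity
strictly below the cutoff (default 32); pixels *at or above* the cutoff
are background. The equality case is deliberately assigned to
background — this follows the procedure's stated rule even though some
common library implementations binarize with a strictly-greater
comparison in the other direction. The threshold simultaneously
reverses black and white: dark luminescent signal becomes white (255)
foreground.

**External contours.** Foreground is 8-connected, background
4-connected — the standard pairing under which outer borders are well
defined. One closed contour is traced per *top-level* component
(Suzuki–Abe-style border following); hole borders and components nested
inside holes are not reported. Discovery is by raster scan and each
trace starts at the component's first-scanned pixel, so identical masks
give identical contour lists. Orientation is clockwise as displayed
(counter-clockwise in right-handed coordinates). Border pixels of
one-pixel-wide arms appear once per passage, keeping the trace a
faithful closed polygon.

**Chain-simple compression.** A vertex is kept exactly when the Freeman
chain direction of its incoming edge differs from its outgoing edge,
i.e. only endpoints of maximal horizontal/vertical/diagonal runs
survive. Compression is exactly geometry-preserving (the dropped
vertices are collinear), so computing area before or after compression
is equivalent; the suite asserts this identity exactly.

**Area.** Absolute shoelace sum over the closed vertex cycle, in
pixel-squared (psq) units; the per-image score is the sum over all
contours, optionally after a minimum-area filter (default off, which
reproduces the unfiltered procedure; a small positive value suppresses
hot pixels in real captures).

### Area convention and its bias

The contour polygon passes through pixel *centers*, so a filled w×h
rectangle scores (w−1)(h−1), not w·h. For hole-free components the
exact relation to the pixel count is the lattice-polygon (Pick)
identity `pixels = area + B/2 + 1`, where B counts the unit chain steps
of the closed traversal (a border pixel traversed twice contributes
twice; an isolated pixel has B = 0). Relative to a continuous target
region the measured area therefore undershoots by O(perimeter), i.e. a
relative error ∝ 1/radius for disk-like foci: about 13% at radius 8,
10% at 12, 6.5% at 16. Group comparisons are unaffected because the
bias is shared by all images quantified with the same settings.

## Statistics

Groups are summarized as arithmetic mean ± standard error, with the
(n−1)-denominator sample standard deviation (the near-universal
convention for "standard error"; undefined and flagged at n = 1).
Groups are compared with the classical pooled-variance two-sample
Student's t-test, two-sided, df = n₁+n₂−2; the unequal-variance form is
not used because the assay names the classical test, and no
multiplicity correction applies to a single comparison. Degenerate
zero-pooled-variance data yield t = 0, p = 1 for equal means and a
flagged infinite t with p = 0 otherwise — common at large effect sizes
where every control area is exactly zero. The implementation is the
explicit pooled formula with the t CDF from scipy; scipy's own
`ttest_ind` serves as an independent cross-check in the tests.

## Synthetic scenes

The generator emulates chemiluminescence-mode CCD captures: a uniform
light background (default level 200), dark foci with a flat **disk**
(depth inside radius) or Gaussian **bell** (`depth·exp(−r²/2σ²)`)
profile, additive i.i.d. Gaussian read noise, clamping to [0, 255] and
half-up rounding to 8 bits. A blob-free scene is the matched negative
control. Raw 8-bit export is assumed — no contrast adjustment is
modeled, since acquisition-side adjustments are not part of the
quantification. Per-image seeds derive from the master seed as
`seed + index`, so datasets reproduce byte-for-byte.

Ground truth is closed-form: the sub-cutoff region of a disk blob is the
full disk (area πr²) whenever `background − depth < cutoff`; for a bell
blob it is a disk of radius ρ with `ρ² = 2σ² ln(depth/(background −
cutoff))` when the log argument exceeds 1. A background below the
cutoff makes the whole frame foreground (frame area returned). The
closed form requires per-blob regions disjoint and inside the frame;
violations raise an unsupported-scene error rather than returning a
silently wrong truth (bell disjointness is guarded at `max(ρ, 3σ)`
because Gaussian tails extend past ρ). Overlapping blobs are rejected
rather than analytically merged, keeping the truth closed-form.

**Default study conditions** (used by the examples, the CLI fixture and
the acceptance script): 64×64 canvas, background 200, noise sd 3, one
centred disk of radius 12 and depth 200, triplicates per group. These
mirror a strong-transduction assay: the focus bottoms out at intensity
0, far below the cutoff, while `P(background pixel < 32)` under
N(200, 3²) is negligible, so controls quantify to exactly zero.

What the generator does *not* model: Poisson shot noise (additive
Gaussian read noise is the simplest model that exercises threshold
robustness), optical point-spread blur, exposure-time accumulation,
vignetting/flat-field structure, luciferin kinetics and 3-D tissue
geometry. Passing tests therefore demonstrate correctness of the
*quantification*, not robustness to every artifact of real captures.

## Numerical and design choices

- Thresholds, masks and images are integer/uint8 throughout; areas are
  exact sums of half-integer cross products, so equality assertions in
  the tests are exact, not tolerance-based.
- Connectivity, external-only retrieval, and the pixel-center area
  convention are documented assumptions of this implementation; the
  underlying procedure statement is silent on them.
- Problem sizes in tests and the acceptance script (64–80 px canvases,
  50–200 seeded replicates) were chosen as the smallest sizes at which
  the discretization bands and rejection-rate estimates are stable.
- Pseudocolor LUTs ship as explicit 256-entry tables because vendor
  pseudocolor mappings are unpublished: `grey` is the identity triplet
  and `fire` is a piecewise-linear black→red→orange→white ramp with
  anchors 0→(0,0,0), 96→(255,64,0), 192→(255,200,0), 255→(255,255,255);
  reference entries 0→(0,0,0), 128→(255,109,0), 255→(255,255,255).
  Display choices never feed back into quantification.
- Batch processing is strict by default (first unreadable file aborts)
  to prevent silently incomplete assay tables; a lenient mode
  skips-with-warning.

## Known limitations

- Area, not integrated intensity: two foci of equal footprint but
  different brightness score identically above/below the cutoff.
- The fixed cutoff of 32 presumes consistent exposure; captures with a
  background darker than the cutoff would quantify the entire frame.
- Components nested inside holes are ignored by design (external
  contours only); rings therefore score their outer area.
- The t-test treats replicate images as independent measurements;
  whether replicates are separate specimens or repeated exposures is an
  assay-design question outside the package.
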