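# bliquant

Contour-area quantification of bioluminescent-imaging (BLI) captures for
viral-vector reporter assays, with a synthetic CCD-scene generator that
provides analytic ground truth.

## The problem

Ex vivo BLI measures viral-vector transduction by imaging light emitted
from luciferase-expressing cells or tissue after luciferin addition.  In
chemiluminescence-mode CCD displays the luminescent signal appears
**dark on a light background**.  A simple, reproducible way to score such
captures is to measure how much of the frame the dark signal occupies:

1. grayscale-transform the capture (Rec. 601 luma, `0.299R + 0.587G + 0.114B`);
2. apply an **inverse-binary threshold** at cutoff 32 — pixels with
   intensity `< 32` become foreground (255), pixels `>= 32` become
   background (0), reversing the roles of black and white;
3. trace the **external contour** of every top-level foreground region
   (Suzuki–Abe-style border following, 8-connected foreground);
4. compress each contour with **chain-approximate-simple** — keep only
   the endpoints of maximal horizontal/vertical/diagonal runs;
5. sum the **shoelace areas** `|Σ (xᵢ yᵢ₊₁ − xᵢ₊₁ yᵢ)| / 2` of all
   contours: the combined area in pixel-squared (**psq**) units is the
   per-image measure of bioluminescence;
6. compare transduced vs untransduced groups (typically triplicates) as
   mean ± SE with a pooled-variance Student's *t*-test.

Because wet-lab captures carry no ground truth, the package includes a
seeded scene generator — dark disk- or bell-profile foci on a light,
noisy background — whose sub-cutoff region area is known in closed form,
so the whole pipeline can be validated against analytic answers.

## Worked example

```bash
python examples/02_quantify_image.py
```

```
image disk12: 1 contour(s)
measured combined area : 408.0 psq
analytic circle area   : 452.4 psq (pi * 12^2 = 452.4)
relative error         : 9.8%
```

A noise-free disk focus of radius 12 px is recovered as a single contour
of 408 psq against the analytic π·12² ≈ 452.4 psq.  The boundary polygon
runs through pixel *centers*, so the measured area systematically
undershoots by roughly one perimeter's worth of half-pixels; the
relative error shrinks like 1/radius as foci grow.

The full assay workflow (`examples/03_compare_groups.py`) simulates
triplicates at the study conditions (background 200, read-noise sd 3,
disk radius 12, depth 200), quantifies them in batch, and prints:

```
signal: mean = 408.0 psq, SE = 0.00 (n = 3)
control: mean = 0.0 psq, SE = 0.00 (n = 3)
Student's t-test: t = inf, df = 4, p = 0.0
```

At this large effect size every control area is exactly zero and the
pooled variance vanishes, so the *t*-statistic degenerates to infinity
with p = 0 — reported as such rather than masked.

The same workflow is available from the shell:

```bash
bliquant simulate --n-per-group 3 --seed 7 --out data/
bliquant quantify --cutoff 32 --out results.csv data/manifest.csv
bliquant compare --results results.csv --out report.csv
bliquant render --mode pseudocolor --lut fire --out view.png data/signal_00.png
```

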