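"""Generate a synthetic signal-vs-control capture set with ground truth.

Renders 3 transduced-style captures (one dark luminescent disk focus,
radius 12 px, depth 200 on background 200 with read-noise sd 3) and 3
matched blob-free controls, then prints the manifest.  true_area_psq is
the closed-form area of the sub-cutoff region — the answer a perfect
quantifier would recover (0 for controls).
"""

import tempfile

from bliquant import default_control_scene, default_signal_scene, make_dataset

out_dir = tempfile.mkdtemp(prefix="bli_dataset_")
manifest = make_dataset(
    signal_spec=default_signal_scene(),
    control_spec=default_control_scene(),
    n_per_group=3,
    seed=7,
    out_dir=out_dir,
)
print(f"wrote {len(manifest)} images to {out_dir}")
print(manifest.to_string(index=False))
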