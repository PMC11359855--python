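"""Display modes: grey scale, pseudocolor, and merge over a photograph.

Renders a noisy signal capture in the three conventional views and
writes them next to a temporary directory.  The merge view blends the
pseudocolored thresholded signal (alpha 0.6) onto a synthetic
"unexposed" photograph; background pixels keep the photograph untouched,
so quantification is unaffected by any display choice.
"""

import tempfile
from pathlib import Path

import numpy as np

from bliquant import (
    default_signal_scene,
    overlay_merge,
    render_pseudocolor,
    render_scene,
    write_image,
)

out_dir = Path(tempfile.mkdtemp(prefix="bli_views_"))
image, _ = render_scene(default_signal_scene(seed=5))
photo = np.full((64, 64, 3), (140, 125, 110), dtype=np.uint8)  # stand-in tissue photo

write_image(render_pseudocolor(image, "grey"), out_dir / "grey.png")
write_image(render_pseudocolor(image, "fire"), out_dir / "pseudocolor.png")
write_image(overlay_merge(photo, image, alpha=0.6, lut="fire"), out_dir / "merge.png")
print(f"wrote grey.png, pseudocolor.png, merge.png to {out_dir}")
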