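#!/usr/bin/env python
"""Generate the phantom study data: a serial-section nerve and channel pairs.

The serial-section phantom emulates coronal sections through an optic nerve:
the mean in-plane fiber angle oscillates with position (three interior
inflections at z = 0.25, 0.5, 0.75, which double as the tissue-environment
transitions) and the fraction of longitudinal (small round) profiles rises
from 0.1 proximally to 0.7 at the chiasm end.  Section images are written as
16-bit TIFFs with the exact ground truth alongside.
"""

import json
from pathlib import Path

import numpy as np

from fiberorient.io import write_image
from fiberorient.phantom import PhantomSpec, generate_series

OUT = Path("results/phantom")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(
        n_sections=60,
        seed=SEED,
        theta_fn=lambda z: 90.0 + 30.0 * np.sin(4.0 * np.pi * z),
        kappa=8.0,
        section_angle_noise_sd_deg=3.0,
        longitudinal_fraction_fn=lambda z: 0.1 + 0.6 * z,
        transitions=(0.25, 0.5, 0.75),
    )
    images, truth = generate_series(spec)
    for i, img in enumerate(images):
        write_image(OUT / f"section_{i:03d}.tif", img)
    truth.to_json(OUT / "truth.json")
    with open(OUT / "spec.json", "w") as fh:
        json.dump(
            {
                "n_sections": spec.n_sections,
                "pixel_size_um": spec.pixel_size_um,
                "image_size_px": list(spec.image_size_px),
                "kappa": spec.kappa,
                "seed": SEED,
                "transitions": list(spec.transitions),
                "true_inflections": truth.inflection_points_true,
            },
            fh,
            indent=1,
        )
    print(f"wrote {len(images)} sections to {OUT}")
    print(f"true interior inflections of theta(z): "
          f"{[round(x, 4) for x in truth.inflection_points_true]}")


if __name__ == "__main__":
    main()
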