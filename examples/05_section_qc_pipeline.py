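"""Section-image QC: accept, analyse or discard.

Renders three synthetic dual-stained sections from known geometry —
a clean central cut of an eccentric spheroid, a sheared (warped) section
and an oblique off-centre cut — and runs the full decision pipeline on
each.  Only the clean section is analysed; the artefacts are caught by
the confocality and concentricity tests.
"""

import numpy as np

from spheroidox import (
    OxygenModelParams,
    SyntheticSectionSpec,
    analyze_section,
    render_section,
    solve_anoxic_geometry,
)

UM = 1e-6
params = OxygenModelParams(p_o=100.0, D=2e-9, a=20.0)
geom = solve_anoxic_geometry("prolate", 488.5 * UM, 0.66, params)

scenarios = {
    "central cut": {},
    "sheared section (x1.3)": {"shear": 1.3},
    "oblique off-centre cut (100 um)": {"cut_offset_um": 100.0},
}

for name, kw in scenarios.items():
    spec = SyntheticSectionSpec(geom, pixel_size_um=2.0, noise_sigma=0.05,
                                rng_seed=7, **kw)
    img, truth = render_section(spec)
    rep = analyze_section(img, 2.0, params)
    line = f"{name:34s} decision={rep.decision.value:9s} "
    line += f"confocality err={rep.confocality_rel_error:5.1%} "
    line += f"concentric={str(rep.concentric):5s}"
    if rep.ocr is not None:
        line += f"  OCR={rep.ocr.a:5.2f} +- {rep.ocr.sigma_a:4.2f} mmHg/s"
    print(line)

print(f"\nGenerator's true OCR was {params.a} mmHg/s; only the clean central"
      "\nsection yields an estimate (combined prolate/oblate form), and the"
      "\ntwo sectioning artefacts are correctly discarded.")
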