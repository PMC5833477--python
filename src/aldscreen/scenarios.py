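"""Ready-made synthetic study designs used by tests, examples and scripts."""

from __future__ import annotations

import pandas as pd

from aldscreen.synth import MixtureSpec, PlateSpec
from aldscreen.wells import ROWS_384


def build_synthetic_screen(seed: int = 0):
    """A 384-well screen with planted ground truth.

    Column 1 is DMSO, column 2 is DEAB; the 352 remaining wells are samples.
    Planted among them: 10 suppressor compounds (60% knockdown of the
    ALDH-high pool), 5 fast-acting enzyme mimics (DEAB-like near-total
    abolition plus the 2 h / wash-off follow-up pattern), and 20 toxic wells
    (cell count reduced to 30%).

    Returns ``(spec, followup, suppressor_wells, mimic_wells, toxic_wells)``
    where ``followup`` is the per-compound 2 h / wash-off effect table.
    """
    layout, compounds, overrides, toxicity = {}, {}, {}, {}
    for r in ROWS_384:
        layout[f"{r}01"] = "dmso"
        layout[f"{r}02"] = "deab"
        for c in range(3, 25):
            w = f"{r}{c:02d}"
            layout[w] = "sample"
            compounds[w] = (f"CPD_{w}", 10.0)

    suppressors = [f"C{c:02d}" for c in range(3, 13)]
    for w in suppressors:
        overrides[w] = {"high_fraction": 0.02}
        compounds[w] = (f"SUP_{w}", 10.0)
    mimics = [f"D{c:02d}" for c in range(3, 8)]
    for w in mimics:
        overrides[w] = {"high_fraction": 0.001}
        compounds[w] = (f"MIM_{w}", 10.0)
    toxic = [f"E{c:02d}" for c in range(3, 13)] + [f"F{c:02d}" for c in range(3, 13)]
    for w in toxic:
        toxicity[w] = 0.3

    spec = PlateSpec(
        layout=layout, compounds=compounds, overrides=overrides,
        toxicity=toxicity,
        base_mixture=MixtureSpec(n_cells=5000, high_fraction=0.05),
        seed=seed,
    )
    followup = pd.DataFrame(
        [{"compound": f"MIM_{w}", "effect_2h": 94.0, "effect_washoff": 5.0}
         for w in mimics]
        + [{"compound": f"SUP_{w}", "effect_2h": 10.0, "effect_washoff": 80.0}
           for w in suppressors]
    )
    return spec, followup, set(suppressors), set(mimics), set(toxic)
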