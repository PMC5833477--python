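"""Detect tumorspheres and score tumorsphere-formation capacity (TFC).

Renders a Day-7 image with four objects — 40, 100 and 300 µm circles plus a
100 µm-equivalent 10:1 ellipse — and debris. Only the 100 µm circle passes
the morphometric filters (50-250 µm equivalent diameter, circularity >= 0.5),
so with 200 seeded cells the TFC is 1/200 = 0.005.
"""

from aldscreen import SphereImageSpec, compute_tfc, detect_spheres, gen_sphere_field
from aldscreen.synth import SphereSpec

spec = SphereImageSpec(
    spheres=[SphereSpec(diameter_um=40), SphereSpec(diameter_um=100),
             SphereSpec(diameter_um=300),
             SphereSpec(diameter_um=100, elongation=10, angle_deg=30)],
    debris_count=3, seed=4,
)
img, truth = gen_sphere_field(spec)
records = detect_spheres(img, spec.pixel_size)
for r in records:
    print(f"object {r.sphere_id}: d={r.equivalent_diameter_um:6.1f} µm, "
          f"circularity={r.shape_factor:.3f}, passes={r.passes_filters}")

tfc = compute_tfc(records, n_seeded=200)
print(f"TFC = {tfc.n_spheres_pass}/{tfc.n_seeded} = {tfc.tfc:.4f}")
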