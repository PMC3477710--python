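"""Compare the 4x1 high-definition ring with the conventional pad montage
on the same head: the ring confines suprathreshold cortex inside its
scalp projection while the pads spread current broadly.

Containment = fraction of cortical locations above half the robust peak
whose radial scalp projection falls inside the ring disc.
"""

import tdcsim as t
from tdcsim.metrics import RingRegion
from tdcsim.montage import _scalp_radius_mm

spec = t.SphereSpec(80, {"skin": 6, "skull": 5, "csf": 3, "gray": 4}, voxel_mm=2.0)
head = t.make_layered_sphere_phantom(spec)

results = {}
for name, preset in [("pad", t.preset_pad_m1_so), ("hd_4x1", t.preset_hd_4x1)]:
    montage = preset(head)
    pot, report, _, _ = t.solve_montage(head, montage)
    ef = t.gradient_to_efield(pot, head)
    cmap = t.normal_component_map(ef, t.extract_cortical_surface(head))
    region = RingRegion(
        center_direction=tuple(montage.anode.direction),
        radius_mm=60.0,
        scalp_radius_mm=_scalp_radius_mm(head),
        center_vox=tuple(head.center_vox),
    )
    rep = t.metrics_report(cmap, region=region)
    results[name] = rep
    print(f"{name}: peak {rep.peak_ef_V_per_m:.3f} V/m, "
          f"suprathreshold volume {rep.focality_volume_mm3:.0f} mm^3, "
          f"containment {rep.containment_fraction:.3f}")

print("\nthe ring montage keeps nearly all suprathreshold cortex inside its "
      "perimeter (containment ~1); the pads modulate cortex far outside it")
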