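# Illustrative "subject" phantom presets emulating inter-individual anatomical
# variation across three healthy adults: head radius varies ~ +/-10% and skull
# thickness spans 4-7 mm.  These are conventions, not reconstructions of any
# real anatomy.  Thicknesses in mm, outside-in; white matter fills the core.
subjects:
  M1:
    outer_radius_mm: 94.0
    layer_thicknesses_mm: {skin: 7.0, skull: 7.0, csf: 4.0, gray: 4.0}
  M2:
    outer_radius_mm: 90.0
    layer_thicknesses_mm: {skin: 6.0, skull: 5.5, csf: 3.0, gray: 4.0}
  F:
    outer_radius_mm: 84.0
    layer_thicknesses_mm: {skin: 5.0, skull: 4.0, csf: 2.5, gray: 4.0}

# Default montage placement angles on a sphere (radians are computed from
# these degrees).  theta is the polar angle from the vertex (+z), phi the
# azimuth.  "m1" approximates C3 (left superior-lateral); "so" approximates
# the right (contralateral) supraorbital ridge.
montage_angles_deg:
  m1: {theta: 45.0, phi: 180.0}
  so: {theta: 70.0, phi: 315.0}
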