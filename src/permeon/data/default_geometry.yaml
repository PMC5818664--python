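# Default channel geometry: lower copy of the two-membrane system.
# Axial intervals are channel-local, half-open [lo, hi), Angstrom,
# +s pointing extracellular.
axis: [0.0, 0.0, 1.0]
axis_origin: [20.0, 20.0, 40.0]
region_bounds:
  intracellular_bulk: [-41.0, -15.0]
  cavity: [-15.0, -5.0]
  sf: [-5.0, 5.0]
  vestibule: [5.0, 12.0]
  extracellular_bulk: [12.0, 41.0]
sf_radius: 4.5
side_portal_width: 5.5   # portal band spans (sf_radius, sf_radius + width]
cavity_radius: 8.0
site_planes:
  # B34 at the T63 carbonyl plane, B23 at the V64 plane; S1-S4 are the
  # adjacent cage midpoints
  B34: -1.2
  B23: 1.0
  S4: -2.3
  S3: -0.1
  S2: 2.1
  S1: 4.3
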