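# Arcuate fasciculus dissection ROIs (MNI152 world mm).
# Two endpoint spheres per hemisphere plus a fronto-parietal stem waypoint.
# The waypoint centers are nominal (defined at the level of the central
# sulcus); adjust per study as needed.
left:
  - {center: [-60.0, -45.0, 0.0], diameter: 20.0, role: endpoint_sphere, label: temporal}
  - {center: [-53.0, 27.0, 20.0], diameter: 30.0, role: endpoint_sphere, label: frontal}
  - {center: [-38.0, -18.0, 30.0], diameter: 16.0, role: waypoint, label: stem}
right:
  - {center: [60.0, -43.0, -1.0], diameter: 20.0, role: endpoint_sphere, label: temporal}
  - {center: [49.0, 27.0, 20.0], diameter: 30.0, role: endpoint_sphere, label: frontal}
  - {center: [38.0, -18.0, 30.0], diameter: 16.0, role: waypoint, label: stem}
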