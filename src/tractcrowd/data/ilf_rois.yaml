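# Inferior longitudinal fasciculus dissection ROIs (MNI152 world mm).
# Occipital and temporal waypoints plus an external-capsule exclusion ROI
# isolating the ventral pathway.  Centers are nominal.
left:
  - {center: [-30.0, -85.0, -10.0], diameter: 24.0, role: waypoint, label: occipital}
  - {center: [-40.0, -8.0, -25.0], diameter: 24.0, role: waypoint, label: temporal}
  - {center: [-33.0, 0.0, 2.0], diameter: 14.0, role: exclusion, label: external_capsule}
right:
  - {center: [30.0, -85.0, -10.0], diameter: 24.0, role: waypoint, label: occipital}
  - {center: [40.0, -8.0, -25.0], diameter: 24.0, role: waypoint, label: temporal}
  - {center: [33.0, 0.0, 2.0], diameter: 14.0, role: exclusion, label: external_capsule}
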