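# Estimated implant and optic-disc landmarks for the four implanted
# subjects (fundus-photography estimates; fovea at the origin, nasal-
# positive x, rotation CCW w.r.t. the horizontal raphe).
subjects:
  - id: "1"
    implant: ArgusI
    array_center_um: [-651.0, -707.0]
    array_rotation_deg: -49.3
    optic_disc_deg: [14.0, 2.40]
    eye: RE
  - id: "2"
    implant: ArgusII
    array_center_um: [-1331.0, -850.0]
    array_rotation_deg: -28.4
    optic_disc_deg: [16.2, 1.38]
    eye: RE
  - id: "3"
    implant: ArgusII
    array_center_um: [-2142.0, 102.0]
    array_rotation_deg: -53.9
    optic_disc_deg: [17.7, 1.45]
    eye: RE
  - id: "4"
    implant: ArgusII
    array_center_um: [-1807.0, 401.0]
    array_rotation_deg: -22.1
    optic_disc_deg: [16.3, 2.37]
    eye: RE
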