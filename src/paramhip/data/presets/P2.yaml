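# Parameterised model P2 (right hip, segmentation-based equivalent S2).
depth_d: 0.6
anterior_cut_center_o1: [15.3, -12.5]
anterior_cut_radius_r1: 32.6
fossa_center_o2: [6.39, -1.32]
fossa_radius_r2: 14.2
cavity_radius: 29.0
cartilage_thickness_t: 2.0
radial_clearance: 0.5
inclination_deg: 63.0
anteversion_deg: 15.0
side: right
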