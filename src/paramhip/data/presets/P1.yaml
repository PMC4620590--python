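# Parameterised model P1 (left hip, segmentation-based equivalent S1b).
depth_d: 1.2
anterior_cut_center_o1: [22.08, -18.78]
anterior_cut_radius_r1: 43.8
fossa_center_o2: [5.63, -2.35]
fossa_radius_r2: 16.9
cavity_radius: 30.0
cartilage_thickness_t: 2.0
radial_clearance: 0.5
inclination_deg: 63.0
anteversion_deg: 15.0
side: left
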