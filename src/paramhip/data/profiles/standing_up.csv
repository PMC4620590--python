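# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 190 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-16.728,28.580,-24.133
4,-16.914,31.052,-25.796
8,-17.800,35.079,-28.476
12,-19.665,41.336,-32.615
16,-22.788,50.498,-38.586
20,-27.408,62.998,-46.525
24,-33.660,78.713,-56.179
28,-41.483,96.689,-66.810
32,-50.508,115.054,-77.248
36,-59.960,131.243,-86.088
40,-68.678,142.560,-92.002
44,-75.288,146.917,-94.060
48,-78.554,143.470,-91.957
52,-77.774,132.893,-86.073
56,-73.049,117.149,-77.358
60,-65.284,98.880,-67.084
64,-55.893,80.671,-56.564
68,-46.366,64.485,-46.897
72,-37.862,51.406,-38.814
76,-31.011,41.696,-32.632
80,-25.920,35.043,-28.308
84,-22.342,30.841,-25.558
88,-19.874,28.431,-23.984
92,-18.124,27.233,-23.185
96,-16.795,26.804,-22.825
100,-15.707,26.834,-22.659
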