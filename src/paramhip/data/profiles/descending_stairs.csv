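# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 260 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-34.416,58.447,-51.514
4,-43.116,83.616,-71.676
8,-56.803,126.067,-104.272
12,-67.223,169.339,-134.374
16,-65.631,183.887,-139.501
20,-52.593,158.691,-114.947
24,-37.072,115.568,-80.007
28,-27.088,83.415,-55.372
32,-25.093,73.235,-46.871
36,-30.655,82.066,-51.031
40,-43.764,105.143,-64.148
44,-64.528,137.535,-83.281
48,-90.359,170.372,-103.697
52,-114.279,191.337,-118.598
56,-127.336,191.007,-122.074
60,-124.272,169.181,-112.682
64,-107.425,134.907,-94.377
68,-84.854,100.206,-73.941
72,-64.639,73.359,-57.105
76,-50.674,56.604,-46.299
80,-42.592,48.027,-40.966
84,-38.132,44.547,-39.213
88,-35.214,43.723,-39.236
92,-32.663,44.148,-39.868
96,-30.050,45.153,-40.517
100,-27.342,46.433,-40.926
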