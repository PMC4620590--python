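# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 233 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-29.524,50.139,-44.192
4,-36.943,70.567,-60.639
8,-50.591,108.792,-90.396
12,-64.060,153.809,-122.814
16,-67.342,177.226,-135.444
20,-57.315,160.739,-117.366
24,-41.275,119.081,-83.111
28,-28.890,82.563,-55.234
32,-24.908,68.077,-43.877
36,-30.085,76.432,-47.810
40,-44.253,102.448,-62.787
44,-64.906,135.399,-82.222
48,-84.056,157.412,-95.905
52,-91.257,153.772,-95.216
56,-82.735,126.341,-80.493
60,-65.290,91.357,-60.528
64,-49.191,63.979,-44.435
68,-39.547,48.636,-35.570
72,-35.407,41.988,-32.357
76,-33.871,39.574,-32.029
80,-32.946,38.803,-32.758
84,-31.840,38.699,-33.752
88,-30.375,38.989,-34.727
92,-28.580,39.586,-35.562
96,-26.550,40.428,-36.182
100,-24.408,41.450,-36.533
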