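# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 231 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-36.922,63.452,-51.300
4,-39.757,71.285,-57.064
8,-43.081,80.500,-63.501
12,-46.928,91.006,-70.471
16,-51.324,102.593,-77.772
20,-56.285,114.913,-85.150
24,-61.796,127.487,-92.322
28,-67.791,139.723,-98.997
32,-74.131,150.962,-104.904
36,-80.583,160.535,-109.813
40,-86.822,167.837,-113.546
44,-92.443,172.392,-115.981
48,-97.007,173.920,-117.058
52,-100.095,172.361,-116.764
56,-101.370,167.886,-115.130
60,-100.637,160.862,-112.229
64,-97.874,151.806,-108.165
68,-93.244,141.313,-103.082
72,-87.067,129.992,-97.159
76,-79.777,118.409,-90.607
80,-71.861,107.050,-83.665
84,-63.795,96.297,-76.583
88,-55.998,86.427,-69.606
92,-48.794,77.616,-62.956
96,-42.398,69.952,-56.812
100,-36.922,63.452,-51.300
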