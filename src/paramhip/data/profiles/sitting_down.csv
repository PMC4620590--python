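# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 156 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-13.232,22.606,-19.089
4,-12.944,23.764,-19.741
8,-12.965,25.551,-20.741
12,-13.450,28.271,-22.307
16,-14.577,32.303,-24.683
20,-16.552,38.045,-28.096
24,-19.591,45.813,-32.698
28,-23.900,55.706,-38.492
32,-29.611,67.452,-45.288
36,-36.693,80.314,-52.682
40,-44.851,93.100,-60.083
44,-53.458,104.318,-66.787
48,-61.578,112.465,-72.084
52,-68.104,116.369,-75.371
56,-72.009,115.480,-76.256
60,-72.621,109.994,-74.624
64,-69.825,100.779,-70.663
68,-64.096,89.145,-64.831
72,-56.367,76.529,-57.783
76,-47.763,64.221,-50.259
80,-39.333,53.176,-42.957
84,-31.842,43.955,-36.426
88,-25.690,36.751,-31.003
92,-20.950,31.479,-26.800
96,-17.470,27.881,-23.742
100,-14.994,25.617,-21.631
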