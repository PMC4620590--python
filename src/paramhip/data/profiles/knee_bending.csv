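# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 143 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-15.346,26.062,-22.971
4,-15.485,28.706,-24.790
8,-16.049,32.460,-27.222
12,-17.157,37.583,-30.392
16,-18.932,44.283,-34.356
20,-21.501,52.628,-39.061
24,-24.986,62.459,-44.323
28,-29.471,73.322,-49.838
32,-34.945,84.449,-55.214
36,-41.230,94.817,-60.029
40,-47.931,103.299,-63.890
44,-54.433,108.864,-66.491
48,-59.973,110.801,-67.641
52,-63.787,108.876,-67.278
56,-65.292,103.382,-65.456
60,-64.241,95.065,-62.335
64,-60.786,84.945,-58.164
68,-55.437,74.104,-53.261
72,-48.926,63.501,-47.983
76,-42.028,53.856,-42.698
80,-35.411,45.606,-37.735
84,-29.531,38.933,-33.346
88,-24.615,33.819,-29.681
92,-20.689,30.117,-26.779
96,-17.652,27.612,-24.583
100,-15.346,26.062,-22.971
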