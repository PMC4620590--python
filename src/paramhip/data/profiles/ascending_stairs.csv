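# Representative synthetic activity profile (constructed for paramhip;
# smooth magnitude shape, peak resultant 252 %BW, directed into the
# acetabular roof). Right-hip model frame: x anterior, y superior, z lateral.
cycle_pct,fx_pcBW,fy_pcBW,fz_pcBW
0,-32.763,55.297,-50.846
4,-39.909,74.728,-67.042
8,-52.698,109.495,-94.805
12,-67.266,153.848,-127.442
16,-76.144,188.519,-148.459
20,-73.855,193.132,-144.047
24,-61.853,165.806,-116.998
28,-47.393,126.186,-84.386
32,-38.248,98.227,-62.549
36,-39.037,94.400,-57.679
40,-50.853,113.799,-67.431
44,-71.268,146.048,-85.039
48,-93.448,174.607,-101.427
52,-107.576,183.426,-108.015
56,-106.662,166.808,-101.152
60,-92.000,133.111,-84.281
64,-71.867,97.333,-65.046
68,-54.684,70.332,-49.944
72,-43.936,54.572,-41.269
76,-38.544,47.115,-37.849
80,-35.958,44.145,-37.422
84,-34.280,43.173,-38.227
88,-32.639,43.066,-39.327
92,-30.799,43.425,-40.321
96,-28.782,44.112,-41.046
100,-26.695,45.056,-41.428
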