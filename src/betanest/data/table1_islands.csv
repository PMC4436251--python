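island,lat,lon,area_ha,isolation,habitat_richness,richness_birds,richness_lizards
1,29.519844,118.873853,1289.23,0.78,7,43,5
2,29.508375,118.819253,143.19,0.88,6,34,4
3,29.519403,118.921089,109.03,0.73,6,35,4
4,29.530978,118.940131,55.08,0.79,5,32,4
5,29.494456,118.894186,46.37,0.68,5,31,3
6,29.514694,118.8493,35.64,0.63,5,27,4
7,29.535214,118.937172,32.29,0.88,5,30,3
8,29.495844,118.928394,5.69,0.57,3,30,2
9,29.618778,118.967561,3.42,0.69,4,24,0
10,29.500531,118.885831,2.9,0.67,3,20,1
11,29.498581,118.903867,2.83,0.77,4,25,2
12,29.496047,118.906244,2.29,0.77,4,26,3
13,29.549533,118.910472,2.23,0.98,3,23,0
14,29.567592,118.895033,2.0,0.74,3,23,2
15,29.612514,118.950108,1.93,0.73,4,24,1
16,29.503481,118.891964,1.74,0.66,3,20,2
17,29.495381,118.909292,1.54,0.76,3,25,1
18,29.507797,118.823467,1.52,0.71,3,24,1
19,29.520722,118.827428,1.4,0.68,3,23,1
20,29.482164,118.915414,1.26,0.42,3,25,1
21,29.490125,118.900422,1.2,0.67,3,22,1
22,29.503131,118.890383,1.2,0.67,3,23,2
23,29.505322,118.894081,1.17,0.63,3,20,2
24,29.579878,118.911989,1.15,0.67,3,23,0
25,29.576881,118.927358,1.03,0.8,3,18,1
26,29.529292,118.922656,1.01,0.72,3,24,1
27,29.551892,118.907267,0.96,0.98,3,19,0
28,29.614225,118.961944,0.91,0.74,4,23,0
29,29.530031,118.921681,0.86,0.7,3,22,1
30,29.515153,118.822533,0.83,0.74,3,22,1
31,29.613417,118.953589,0.83,0.75,4,20,0
32,29.529756,118.924539,0.8,0.74,2,25,1
33,29.566167,118.895519,0.73,0.8,3,23,2
34,29.577386,118.916067,0.67,0.75,3,18,1
35,29.577822,118.9095,0.59,0.68,3,25,0
36,29.495197,118.905239,0.59,0.78,3,21,1
37,29.547833,118.911894,0.57,0.95,3,19,0
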