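eccentricity_mm,density_cells_per_mm2
0.0,0.00
0.5,32715.20
1.0,28515.59
1.5,20949.89
2.0,15001.90
2.5,10704.67
3.0,7662.98
3.5,5522.28
4.0,4016.43
4.5,2954.87
5.0,2203.51
5.5,1668.67
6.0,1285.11
6.5,1007.50
7.0,804.32
7.5,653.66
8.0,540.27
8.5,453.50
9.0,385.93
9.5,332.35
10.0,289.08
10.5,253.54
11.0,223.86
11.5,198.73
12.0,177.18
12.5,158.49
13.0,142.15
13.5,127.75
14.0,115.00
14.5,103.64
15.0,93.49
15.5,84.40
16.0,76.23
16.5,68.88
17.0,62.27
17.5,56.30
18.0,50.91
18.5,46.04
19.0,41.65
19.5,37.67
20.0,34.08
20.5,30.83
21.0,27.90
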