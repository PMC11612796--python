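eccentricity_mm,density_cells_per_mm2
0.0,0.00
0.5,25281.53
1.0,21300.85
1.5,15106.87
2.0,10424.98
2.5,7153.30
3.0,4911.16
3.5,3383.52
4.0,2343.83
4.5,1635.37
5.0,1151.29
5.5,819.18
6.0,590.10
6.5,431.03
7.0,319.64
7.5,240.87
8.0,184.52
8.5,143.67
9.0,113.63
9.5,91.18
10.0,74.14
10.5,60.98
11.0,50.66
11.5,42.44
12.0,35.80
12.5,30.37
13.0,25.88
13.5,22.14
14.0,18.99
14.5,16.33
15.0,14.07
15.5,12.13
16.0,10.48
16.5,9.06
17.0,7.83
17.5,6.78
18.0,5.87
18.5,5.08
19.0,4.40
19.5,3.81
20.0,3.30
20.5,2.86
21.0,2.48
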