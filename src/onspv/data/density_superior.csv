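eccentricity_mm,density_cells_per_mm2
0.0,0.00
0.5,28943.21
1.0,24818.41
1.5,17926.09
2.0,12609.71
2.5,8829.62
3.0,6194.88
3.5,4368.91
4.0,3104.34
4.5,2226.99
5.0,1616.15
5.5,1188.70
6.0,887.60
6.5,673.75
7.0,520.32
7.5,408.93
8.0,326.96
8.5,265.70
9.0,219.15
9.5,183.17
10.0,154.86
10.5,132.21
11.0,113.78
11.5,98.56
12.0,85.84
12.5,75.07
13.0,65.88
13.5,57.96
14.0,51.10
14.5,45.12
15.0,39.89
15.5,35.30
16.0,31.26
16.5,27.70
17.0,24.56
17.5,21.78
18.0,19.32
18.5,17.14
19.0,15.21
19.5,13.50
20.0,11.98
20.5,10.63
21.0,9.44
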