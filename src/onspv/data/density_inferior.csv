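eccentricity_mm,density_cells_per_mm2
0.0,0.00
0.5,27904.29
1.0,23920.48
1.5,17269.80
2.0,12140.07
2.5,8492.76
3.0,5950.68
3.5,4189.11
4.0,2969.38
4.5,2123.44
5.0,1534.79
5.5,1123.22
6.0,833.65
6.5,628.34
7.0,481.39
7.5,375.03
8.0,297.05
8.5,239.06
9.0,195.25
9.5,161.61
10.0,135.33
10.5,114.47
11.0,97.65
11.5,83.88
12.0,72.46
12.5,62.88
13.0,54.77
13.5,47.84
14.0,41.88
14.5,36.73
15.0,32.26
15.5,28.37
16.0,24.96
16.5,21.98
17.0,19.36
17.5,17.07
18.0,15.05
18.5,13.27
19.0,11.70
19.5,10.32
20.0,9.11
20.5,8.03
21.0,7.09
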