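case,organ,method,dose_gy_per_gbq
1,kidneys,OLINDA1.1,0.84
1,kidneys,VoxelMed,0.99
1,liver,OLINDA1.1,0.13
1,liver,VoxelMed,0.11
1,spleen,OLINDA1.1,1.34
1,spleen,VoxelMed,1.26
2,kidneys,OLINDA1.1,0.69
2,kidneys,VoxelMed,0.83
2,liver,OLINDA1.1,0.08
2,liver,VoxelMed,0.09
2,spleen,OLINDA1.1,0.57
2,spleen,VoxelMed,0.7
3,kidneys,OLINDA1.1,0.42
3,kidneys,VoxelMed,0.52
3,liver,OLINDA1.1,0.15
3,liver,VoxelMed,0.16
3,spleen,OLINDA1.1,0.28
3,spleen,VoxelMed,0.3
4,kidneys,OLINDA1.1,0.44
4,kidneys,VoxelMed,0.46
4,liver,OLINDA1.1,
4,liver,VoxelMed,
4,spleen,OLINDA1.1,0.21
4,spleen,VoxelMed,0.25
5,kidneys,OLINDA1.1,0.56
5,kidneys,VoxelMed,0.67
5,liver,OLINDA1.1,0.38
5,liver,VoxelMed,0.42
5,spleen,OLINDA1.1,0.06
5,spleen,VoxelMed,0.07
6,kidneys,OLINDA1.1,0.33
6,kidneys,VoxelMed,0.39
6,liver,OLINDA1.1,1.11
6,liver,VoxelMed,1.47
6,spleen,OLINDA1.1,0.24
6,spleen,VoxelMed,0.27
7,kidneys,OLINDA1.1,0.57
7,kidneys,VoxelMed,0.59
7,liver,OLINDA1.1,0.13
7,liver,VoxelMed,0.12
7,spleen,OLINDA1.1,0.88
7,spleen,VoxelMed,0.8
8,kidneys,OLINDA1.1,0.42
8,kidneys,VoxelMed,0.52
8,liver,OLINDA1.1,0.05
8,liver,VoxelMed,0.05
8,spleen,OLINDA1.1,0.2
8,spleen,VoxelMed,0.22
9,kidneys,OLINDA1.1,0.79
9,kidneys,VoxelMed,0.79
9,liver,OLINDA1.1,0.06
9,liver,VoxelMed,0.07
9,spleen,OLINDA1.1,0.48
9,spleen,VoxelMed,0.52
10,kidneys,OLINDA1.1,1.3
10,kidneys,VoxelMed,1.63
10,liver,OLINDA1.1,0.23
10,liver,VoxelMed,0.27
10,spleen,OLINDA1.1,0.91
10,spleen,VoxelMed,1.14
11,kidneys,OLINDA1.1,0.76
11,kidneys,VoxelMed,0.91
11,liver,OLINDA1.1,0.4
11,liver,VoxelMed,0.33
11,spleen,OLINDA1.1,0.59
11,spleen,VoxelMed,0.96
12,kidneys,OLINDA1.1,0.55
12,kidneys,VoxelMed,0.8
12,liver,OLINDA1.1,0.15
12,liver,VoxelMed,0.16
12,spleen,OLINDA1.1,0.27
12,spleen,VoxelMed,0.3
13,kidneys,OLINDA1.1,0.43
13,kidneys,VoxelMed,0.49
13,liver,OLINDA1.1,0.04
13,liver,VoxelMed,0.04
13,spleen,OLINDA1.1,0.15
13,spleen,VoxelMed,0.14
14,kidneys,OLINDA1.1,0.33
14,kidneys,VoxelMed,0.4
14,liver,OLINDA1.1,0.08
14,liver,VoxelMed,0.09
14,spleen,OLINDA1.1,
14,spleen,VoxelMed,
15,kidneys,OLINDA1.1,0.66
15,kidneys,VoxelMed,0.75
15,liver,OLINDA1.1,0.17
15,liver,VoxelMed,0.18
15,spleen,OLINDA1.1,1.08
15,spleen,VoxelMed,1.18
16,kidneys,OLINDA1.1,0.27
16,kidneys,VoxelMed,0.31
16,liver,OLINDA1.1,0.03
16,liver,VoxelMed,0.03
16,spleen,OLINDA1.1,0.17
16,spleen,VoxelMed,0.18
17,kidneys,OLINDA1.1,1.89
17,kidneys,VoxelMed,2.26
17,liver,OLINDA1.1,0.45
17,liver,VoxelMed,0.51
17,spleen,OLINDA1.1,1.26
17,spleen,VoxelMed,1.44
18,kidneys,OLINDA1.1,0.78
18,kidneys,VoxelMed,0.9
18,liver,OLINDA1.1,0.18
18,liver,VoxelMed,0.21
18,spleen,OLINDA1.1,0.98
18,spleen,VoxelMed,1.12
19,kidneys,OLINDA1.1,0.9
19,kidneys,VoxelMed,1.03
19,liver,OLINDA1.1,0.15
19,liver,VoxelMed,0.17
19,spleen,OLINDA1.1,1.09
19,spleen,VoxelMed,1.13
20,kidneys,OLINDA1.1,0.68
20,kidneys,VoxelMed,0.8
20,liver,OLINDA1.1,0.08
20,liver,VoxelMed,0.09
20,spleen,OLINDA1.1,0.76
20,spleen,VoxelMed,0.89
21,kidneys,OLINDA1.1,0.47
21,kidneys,VoxelMed,0.55
21,liver,OLINDA1.1,0.2
21,liver,VoxelMed,0.22
21,spleen,OLINDA1.1,0.41
21,spleen,VoxelMed,0.45
22,kidneys,OLINDA1.1,0.55
22,kidneys,VoxelMed,0.66
22,liver,OLINDA1.1,0.24
22,liver,VoxelMed,0.26
22,spleen,OLINDA1.1,0.73
22,spleen,VoxelMed,0.85
23,kidneys,OLINDA1.1,0.57
23,kidneys,VoxelMed,0.53
23,liver,OLINDA1.1,0.22
23,liver,VoxelMed,0.25
23,spleen,OLINDA1.1,1.14
23,spleen,VoxelMed,1.33
24,kidneys,OLINDA1.1,0.53
24,kidneys,VoxelMed,0.61
24,liver,OLINDA1.1,0.11
24,liver,VoxelMed,0.12
24,spleen,OLINDA1.1,0.45
24,spleen,VoxelMed,0.5
25,kidneys,OLINDA1.1,1.04
25,kidneys,VoxelMed,1.01
25,liver,OLINDA1.1,0.14
25,liver,VoxelMed,0.15
25,spleen,OLINDA1.1,0.65
25,spleen,VoxelMed,0.72
26,kidneys,OLINDA1.1,0.54
26,kidneys,VoxelMed,0.65
26,liver,OLINDA1.1,0.11
26,liver,VoxelMed,0.11
26,spleen,OLINDA1.1,0.54
26,spleen,VoxelMed,0.59
27,kidneys,OLINDA1.1,0.27
27,kidneys,VoxelMed,0.31
27,liver,OLINDA1.1,0.08
27,liver,VoxelMed,0.09
27,spleen,OLINDA1.1,
27,spleen,VoxelMed,
28,kidneys,OLINDA1.1,0.37
28,kidneys,VoxelMed,0.43
28,liver,OLINDA1.1,0.11
28,liver,VoxelMed,0.13
28,spleen,OLINDA1.1,0.57
28,spleen,VoxelMed,0.65
29,kidneys,OLINDA1.1,0.5
29,kidneys,VoxelMed,0.49
29,liver,OLINDA1.1,0.06
29,liver,VoxelMed,0.07
29,spleen,OLINDA1.1,0.5
29,spleen,VoxelMed,0.48
30,kidneys,OLINDA1.1,1.0
30,kidneys,VoxelMed,1.08
30,liver,OLINDA1.1,0.1
30,liver,VoxelMed,0.1
30,spleen,OLINDA1.1,0.67
30,spleen,VoxelMed,0.68
31,kidneys,OLINDA1.1,0.38
31,kidneys,VoxelMed,0.4
31,liver,OLINDA1.1,0.22
31,liver,VoxelMed,0.22
31,spleen,OLINDA1.1,0.16
31,spleen,VoxelMed,0.17
32,kidneys,OLINDA1.1,0.34
32,kidneys,VoxelMed,0.4
32,liver,OLINDA1.1,1.0
32,liver,VoxelMed,1.13
32,spleen,OLINDA1.1,0.44
32,spleen,VoxelMed,0.54
33,kidneys,OLINDA1.1,0.31
33,kidneys,VoxelMed,0.35
33,liver,OLINDA1.1,0.12
33,liver,VoxelMed,0.12
33,spleen,OLINDA1.1,0.22
33,spleen,VoxelMed,0.24
34,kidneys,OLINDA1.1,0.48
34,kidneys,VoxelMed,0.39
34,liver,OLINDA1.1,0.13
34,liver,VoxelMed,0.13
34,spleen,OLINDA1.1,0.28
34,spleen,VoxelMed,0.23
35,kidneys,OLINDA1.1,0.26
35,kidneys,VoxelMed,0.3
35,liver,OLINDA1.1,0.02
35,liver,VoxelMed,0.02
35,spleen,OLINDA1.1,0.08
35,spleen,VoxelMed,0.09
36,kidneys,OLINDA1.1,0.64
36,kidneys,VoxelMed,0.75
36,liver,OLINDA1.1,0.11
36,liver,VoxelMed,0.12
36,spleen,OLINDA1.1,0.73
36,spleen,VoxelMed,0.84
37,kidneys,OLINDA1.1,0.62
37,kidneys,VoxelMed,0.71
37,liver,OLINDA1.1,0.34
37,liver,VoxelMed,0.37
37,spleen,OLINDA1.1,1.76
37,spleen,VoxelMed,1.94
38,kidneys,OLINDA1.1,0.5
38,kidneys,VoxelMed,0.56
38,liver,OLINDA1.1,0.11
38,liver,VoxelMed,0.12
38,spleen,OLINDA1.1,0.55
38,spleen,VoxelMed,0.62
39,kidneys,OLINDA1.1,0.85
39,kidneys,VoxelMed,0.99
39,liver,OLINDA1.1,0.14
39,liver,VoxelMed,0.16
39,spleen,OLINDA1.1,1.24
39,spleen,VoxelMed,1.4
40,kidneys,OLINDA1.1,0.59
40,kidneys,VoxelMed,0.67
40,liver,OLINDA1.1,0.06
40,liver,VoxelMed,0.07
40,spleen,OLINDA1.1,0.51
40,spleen,VoxelMed,0.56
41,kidneys,OLINDA1.1,0.29
41,kidneys,VoxelMed,0.33
41,liver,OLINDA1.1,0.79
41,liver,VoxelMed,0.91
41,spleen,OLINDA1.1,0.24
41,spleen,VoxelMed,0.26
42,kidneys,OLINDA1.1,0.52
42,kidneys,VoxelMed,0.6
42,liver,OLINDA1.1,0.13
42,liver,VoxelMed,0.14
42,spleen,OLINDA1.1,0.43
42,spleen,VoxelMed,0.47
43,kidneys,OLINDA1.1,0.27
43,kidneys,VoxelMed,0.3
43,liver,OLINDA1.1,0.03
43,liver,VoxelMed,0.03
43,spleen,OLINDA1.1,0.12
43,spleen,VoxelMed,0.13
44,kidneys,OLINDA1.1,0.18
44,kidneys,VoxelMed,0.2
44,liver,OLINDA1.1,0.23
44,liver,VoxelMed,0.25
44,spleen,OLINDA1.1,0.45
44,spleen,VoxelMed,0.5
45,kidneys,OLINDA1.1,0.86
45,kidneys,VoxelMed,1.09
45,liver,OLINDA1.1,0.05
45,liver,VoxelMed,0.06
45,spleen,OLINDA1.1,0.35
45,spleen,VoxelMed,0.41
46,kidneys,OLINDA1.1,0.5
46,kidneys,VoxelMed,0.58
46,liver,OLINDA1.1,0.08
46,liver,VoxelMed,0.09
46,spleen,OLINDA1.1,0.29
46,spleen,VoxelMed,0.33
47,kidneys,OLINDA1.1,0.4
47,kidneys,VoxelMed,0.45
47,liver,OLINDA1.1,0.05
47,liver,VoxelMed,0.06
47,spleen,OLINDA1.1,0.7
47,spleen,VoxelMed,0.76
48,kidneys,OLINDA1.1,0.69
48,kidneys,VoxelMed,0.78
48,liver,OLINDA1.1,0.11
48,liver,VoxelMed,0.12
48,spleen,OLINDA1.1,1.11
48,spleen,VoxelMed,1.24
49,kidneys,OLINDA1.1,0.6
49,kidneys,VoxelMed,0.55
49,liver,OLINDA1.1,0.07
49,liver,VoxelMed,0.08
49,spleen,OLINDA1.1,1.45
49,spleen,VoxelMed,1.34
50,kidneys,OLINDA1.1,0.65
50,kidneys,VoxelMed,0.76
50,liver,OLINDA1.1,0.03
50,liver,VoxelMed,0.02
50,spleen,OLINDA1.1,0.23
50,spleen,VoxelMed,0.26
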