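case,organ,method,dose_gy_per_gbq
1,kidneys,OLINDA1.1,0.62
1,kidneys,VoxelMed,0.54
1,kidneys,VoxelMed_lambdaRD,0.54
1,kidneys,RAYDOSE,0.54
1,liver,OLINDA1.1,0.04
1,liver,VoxelMed,0.03
1,liver,VoxelMed_lambdaRD,0.03
1,liver,RAYDOSE,0.03
1,spleen,OLINDA1.1,1.11
1,spleen,VoxelMed,1.05
1,spleen,VoxelMed_lambdaRD,1.08
1,spleen,RAYDOSE,1.04
2,kidneys,OLINDA1.1,0.4
2,kidneys,VoxelMed,0.36
2,kidneys,VoxelMed_lambdaRD,0.37
2,kidneys,RAYDOSE,0.4
2,liver,OLINDA1.1,0.23
2,liver,VoxelMed,0.2
2,liver,VoxelMed_lambdaRD,0.22
2,liver,RAYDOSE,0.22
2,spleen,OLINDA1.1,0.16
2,spleen,VoxelMed,0.16
2,spleen,VoxelMed_lambdaRD,0.16
2,spleen,RAYDOSE,0.2
3,kidneys,OLINDA1.1,0.87
3,kidneys,VoxelMed,0.76
3,kidneys,VoxelMed_lambdaRD,0.77
3,kidneys,RAYDOSE,0.78
3,liver,OLINDA1.1,0.4
3,liver,VoxelMed,0.37
3,liver,VoxelMed_lambdaRD,0.38
3,liver,RAYDOSE,0.38
3,spleen,OLINDA1.1,0.58
3,spleen,VoxelMed,0.47
3,spleen,VoxelMed_lambdaRD,0.49
3,spleen,RAYDOSE,0.49
4,kidneys,OLINDA1.1,0.32
4,kidneys,VoxelMed,0.28
4,kidneys,VoxelMed_lambdaRD,0.29
4,kidneys,RAYDOSE,0.29
4,liver,OLINDA1.1,0.12
4,liver,VoxelMed,0.11
4,liver,VoxelMed_lambdaRD,0.12
4,liver,RAYDOSE,0.12
4,spleen,OLINDA1.1,0.22
4,spleen,VoxelMed,0.19
4,spleen,VoxelMed_lambdaRD,0.2
4,spleen,RAYDOSE,0.19
5,kidneys,OLINDA1.1,0.42
5,kidneys,VoxelMed,0.36
5,kidneys,VoxelMed_lambdaRD,0.36
5,kidneys,RAYDOSE,0.37
5,liver,OLINDA1.1,0.04
5,liver,VoxelMed,0.03
5,liver,VoxelMed_lambdaRD,0.04
5,liver,RAYDOSE,0.04
5,spleen,OLINDA1.1,0.12
5,spleen,VoxelMed,0.1
5,spleen,VoxelMed_lambdaRD,0.12
5,spleen,RAYDOSE,0.11
6,kidneys,OLINDA1.1,0.52
6,kidneys,VoxelMed,0.44
6,kidneys,VoxelMed_lambdaRD,0.46
6,kidneys,RAYDOSE,0.46
6,liver,OLINDA1.1,0.11
6,liver,VoxelMed,0.1
6,liver,VoxelMed_lambdaRD,0.11
6,liver,RAYDOSE,0.11
6,spleen,OLINDA1.1,0.92
6,spleen,VoxelMed,0.83
6,spleen,VoxelMed_lambdaRD,0.87
6,spleen,RAYDOSE,0.84
7,kidneys,OLINDA1.1,0.39
7,kidneys,VoxelMed,0.33
7,kidneys,VoxelMed_lambdaRD,0.34
7,kidneys,RAYDOSE,0.34
7,liver,OLINDA1.1,0.1
7,liver,VoxelMed,0.08
7,liver,VoxelMed_lambdaRD,0.08
7,liver,RAYDOSE,0.09
7,spleen,OLINDA1.1,0.46
7,spleen,VoxelMed,0.39
7,spleen,VoxelMed_lambdaRD,0.44
7,spleen,RAYDOSE,0.43
8,kidneys,OLINDA1.1,0.75
8,kidneys,VoxelMed,0.66
8,kidneys,VoxelMed_lambdaRD,0.66
8,kidneys,RAYDOSE,0.67
8,liver,OLINDA1.1,0.02
8,liver,VoxelMed,0.03
8,liver,VoxelMed_lambdaRD,0.03
8,liver,RAYDOSE,0.03
8,spleen,OLINDA1.1,0.28
8,spleen,VoxelMed,0.24
8,spleen,VoxelMed_lambdaRD,0.27
8,spleen,RAYDOSE,0.26
9,kidneys,OLINDA1.1,0.36
9,kidneys,VoxelMed,0.3
9,kidneys,VoxelMed_lambdaRD,0.3
9,kidneys,RAYDOSE,0.34
9,liver,OLINDA1.1,1.65
9,liver,VoxelMed,1.45
9,liver,VoxelMed_lambdaRD,1.56
9,liver,RAYDOSE,1.55
9,spleen,OLINDA1.1,0.38
9,spleen,VoxelMed,0.31
9,spleen,VoxelMed_lambdaRD,0.33
9,spleen,RAYDOSE,0.36
10,kidneys,OLINDA1.1,0.62
10,kidneys,VoxelMed,0.55
10,kidneys,VoxelMed_lambdaRD,0.56
10,kidneys,RAYDOSE,0.54
10,liver,OLINDA1.1,0.08
10,liver,VoxelMed,0.07
10,liver,VoxelMed_lambdaRD,0.07
10,liver,RAYDOSE,0.08
10,spleen,OLINDA1.1,
10,spleen,VoxelMed,
10,spleen,VoxelMed_lambdaRD,
10,spleen,RAYDOSE,
11,kidneys,OLINDA1.1,0.48
11,kidneys,VoxelMed,0.42
11,kidneys,VoxelMed_lambdaRD,0.45
11,kidneys,RAYDOSE,0.44
11,liver,OLINDA1.1,0.34
11,liver,VoxelMed,0.3
11,liver,VoxelMed_lambdaRD,0.35
11,liver,RAYDOSE,0.33
11,spleen,OLINDA1.1,0.67
11,spleen,VoxelMed,0.58
11,spleen,VoxelMed_lambdaRD,0.9
11,spleen,RAYDOSE,0.84
12,kidneys,OLINDA1.1,0.66
12,kidneys,VoxelMed,0.57
12,kidneys,VoxelMed_lambdaRD,0.56
12,kidneys,RAYDOSE,0.57
12,liver,OLINDA1.1,0.13
12,liver,VoxelMed,0.1
12,liver,VoxelMed_lambdaRD,0.11
12,liver,RAYDOSE,0.12
12,spleen,OLINDA1.1,0.21
12,spleen,VoxelMed,0.17
12,spleen,VoxelMed_lambdaRD,0.18
12,spleen,RAYDOSE,0.19
13,kidneys,OLINDA1.1,0.3
13,kidneys,VoxelMed,0.25
13,kidneys,VoxelMed_lambdaRD,0.26
13,kidneys,RAYDOSE,0.28
13,liver,OLINDA1.1,0.08
13,liver,VoxelMed,0.07
13,liver,VoxelMed_lambdaRD,0.07
13,liver,RAYDOSE,0.08
13,spleen,OLINDA1.1,0.34
13,spleen,VoxelMed,0.28
13,spleen,VoxelMed_lambdaRD,0.33
13,spleen,RAYDOSE,0.34
14,kidneys,OLINDA1.1,0.48
14,kidneys,VoxelMed,0.42
14,kidneys,VoxelMed_lambdaRD,0.42
14,kidneys,RAYDOSE,0.41
14,liver,OLINDA1.1,0.06
14,liver,VoxelMed,0.05
14,liver,VoxelMed_lambdaRD,0.06
14,liver,RAYDOSE,0.06
14,spleen,OLINDA1.1,0.1
14,spleen,VoxelMed,0.08
14,spleen,VoxelMed_lambdaRD,0.09
14,spleen,RAYDOSE,0.09
15,kidneys,OLINDA1.1,0.4
15,kidneys,VoxelMed,0.34
15,kidneys,VoxelMed_lambdaRD,0.36
15,kidneys,RAYDOSE,0.36
15,liver,OLINDA1.1,0.03
15,liver,VoxelMed,0.03
15,liver,VoxelMed_lambdaRD,0.03
15,liver,RAYDOSE,0.04
15,spleen,OLINDA1.1,0.62
15,spleen,VoxelMed,0.54
15,spleen,VoxelMed_lambdaRD,0.68
15,spleen,RAYDOSE,0.66
16,kidneys,OLINDA1.1,0.27
16,kidneys,VoxelMed,0.23
16,kidneys,VoxelMed_lambdaRD,0.25
16,kidneys,RAYDOSE,0.27
16,liver,OLINDA1.1,0.3
16,liver,VoxelMed,0.27
16,liver,VoxelMed_lambdaRD,0.3
16,liver,RAYDOSE,0.29
16,spleen,OLINDA1.1,0.52
16,spleen,VoxelMed,0.41
16,spleen,VoxelMed_lambdaRD,0.45
16,spleen,RAYDOSE,0.45
17,kidneys,OLINDA1.1,0.29
17,kidneys,VoxelMed,0.25
17,kidneys,VoxelMed_lambdaRD,0.24
17,kidneys,RAYDOSE,0.24
17,liver,OLINDA1.1,0.09
17,liver,VoxelMed,0.07
17,liver,VoxelMed_lambdaRD,0.07
17,liver,RAYDOSE,0.07
17,spleen,OLINDA1.1,0.36
17,spleen,VoxelMed,0.29
17,spleen,VoxelMed_lambdaRD,0.28
17,spleen,RAYDOSE,0.27
18,kidneys,OLINDA1.1,0.51
18,kidneys,VoxelMed,0.45
18,kidneys,VoxelMed_lambdaRD,0.43
18,kidneys,RAYDOSE,0.44
18,liver,OLINDA1.1,0.07
18,liver,VoxelMed,0.06
18,liver,VoxelMed_lambdaRD,0.07
18,liver,RAYDOSE,0.07
18,spleen,OLINDA1.1,0.31
18,spleen,VoxelMed,0.24
18,spleen,VoxelMed_lambdaRD,0.24
18,spleen,RAYDOSE,0.23
19,kidneys,OLINDA1.1,0.45
19,kidneys,VoxelMed,0.38
19,kidneys,VoxelMed_lambdaRD,0.4
19,kidneys,RAYDOSE,0.44
19,liver,OLINDA1.1,1.43
19,liver,VoxelMed,1.2
19,liver,VoxelMed_lambdaRD,1.21
19,liver,RAYDOSE,1.2
19,spleen,OLINDA1.1,0.83
19,spleen,VoxelMed,0.69
19,spleen,VoxelMed_lambdaRD,0.93
19,spleen,RAYDOSE,0.95
20,kidneys,OLINDA1.1,0.38
20,kidneys,VoxelMed,0.47
20,kidneys,VoxelMed_lambdaRD,0.48
20,kidneys,RAYDOSE,0.51
20,liver,OLINDA1.1,0.11
20,liver,VoxelMed,0.09
20,liver,VoxelMed_lambdaRD,0.1
20,liver,RAYDOSE,0.11
20,spleen,OLINDA1.1,0.38
20,spleen,VoxelMed,0.3
20,spleen,VoxelMed_lambdaRD,0.33
20,spleen,RAYDOSE,0.35
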