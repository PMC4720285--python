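0 4
0 7
0 9
0 11
0 12
0 22
0 34
0 35
1 9
1 23
1 31
1 35
1 41
2 21
2 30
2 31
2 35
2 36
2 40
3 6
3 39
3 40
4 42
7 8
10 14
10 31
10 41
10 47
11 8
11 12
11 25
11 31
11 32
11 46
12 2
12 3
12 7
12 30
12 31
12 39
13 18
13 36
13 42
14 31
14 33
14 44
15 4
15 25
15 26
15 31
15 48
16 26
16 32
16 44
17 3
17 20
17 48
17 49
18 7
18 29
18 35
18 46
19 23
19 27
19 28
19 29
19 42
19 47
20 8
20 38
20 42
20 43
21 22
21 23
22 6
22 8
22 32
23 30
23 38
23 43
24 5
24 6
24 35
24 43
24 47
25 40
26 38
26 41
27 5
27 9
27 32
27 44
27 47
27 49
28 32
28 49
29 43
30 7
31 7
31 35
31 43
31 44
32 36
32 37
33 9
33 35
33 41
34 7
34 36
34 40
34 42
35 9
35 40
35 44
36 40
37 9
37 44
38 7
38 9
39 48
40 7
40 42
40 47
40 48
41 45
42 44
43 8
43 45
44 47
44 48
45 8
45 49
47 6
49 8
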