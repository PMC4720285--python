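0 1
0 5
0 6
0 7
0 8
0 10
0 12
0 13
0 17
0 18
0 19
1 9
1 18
1 31
2 8
3 4
3 5
3 6
3 8
4 9
6 9
7 8
8 9
10 5
10 6
10 11
10 13
10 15
10 17
11 2
11 5
11 9
11 12
11 13
11 18
12 2
12 6
12 8
12 13
12 18
12 19
13 4
13 5
13 14
13 16
13 34
14 2
14 3
14 5
14 6
14 9
14 16
14 59
15 3
15 5
15 7
15 8
15 56
16 6
16 7
16 8
16 9
16 44
16 45
16 56
17 4
17 8
17 18
17 19
18 2
18 59
19 3
19 5
19 8
20 23
20 25
20 29
20 32
20 33
20 34
20 37
21 26
21 30
21 33
21 35
21 37
21 38
22 28
22 33
22 35
22 37
22 38
23 25
23 28
23 30
23 34
23 35
24 25
24 34
24 35
24 38
26 30
27 28
27 29
27 30
27 32
27 34
27 36
27 37
27 39
28 29
28 30
28 31
28 33
28 34
28 35
28 37
28 38
29 36
29 37
29 55
30 33
30 37
30 38
31 4
31 34
31 36
31 38
32 34
32 36
32 38
32 46
33 4
33 7
33 34
33 39
33 41
33 56
34 37
34 39
35 36
36 38
36 39
37 39
38 39
39 47
40 52
40 56
41 53
41 54
41 58
42 46
42 50
42 56
43 47
43 49
43 56
43 59
44 45
44 50
44 52
44 56
44 59
45 47
45 53
45 55
45 57
45 59
46 48
46 49
46 55
46 58
46 59
47 48
47 53
47 56
47 58
48 9
48 51
48 53
48 56
48 59
49 50
49 54
49 58
50 52
50 53
50 56
50 58
51 55
52 8
53 59
54 56
54 59
55 58
55 59
56 59
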