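0 1
0 2
0 18
0 24
0 27
0 32
0 36
0 39
1 2
1 3
1 6
1 10
1 14
1 22
1 29
1 43
1 45
1 48
1 52
1 55
2 3
2 4
2 6
2 8
2 9
2 20
2 21
2 28
2 31
2 35
2 37
2 39
2 49
3 4
3 5
3 30
3 50
3 56
4 5
4 7
4 41
4 47
4 52
5 7
6 8
7 9
10 8
10 26
10 38
11 2
11 3
11 13
11 16
11 17
11 23
11 28
11 31
11 33
11 34
11 43
11 46
11 53
11 59
12 2
12 8
12 13
12 16
12 22
12 29
12 54
13 56
13 57
14 2
14 30
14 40
15 7
15 8
15 23
17 3
18 6
18 46
19 3
19 6
19 34
19 57
20 7
20 21
20 47
21 25
22 27
22 48
22 58
24 7
25 8
25 33
25 42
26 3
26 42
27 49
31 41
32 9
32 54
35 5
36 6
37 6
37 44
38 5
40 8
41 44
44 45
46 51
50 8
50 58
51 7
52 53
55 6
59 9
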