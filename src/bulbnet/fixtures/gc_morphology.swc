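# SWC export, cell_type=GC
1 1 0 0 0 4 -1
2 4 0.25846097 -2.94502945 0.509901429 0.5 1
3 5 0.783671094 -2.25998585 0.0050553241 0.5 2
4 4 -0.731141076 -3.12007612 -2.31676559 0.5 2
5 5 -0.43516587 -3.30835132 -3.25322228 0.5 4
6 4 -1.40993554 -0.594994532 -3.78754806 0.5 4
7 5 -1.86275485 -1.46687056 -3.60103569 0.5 6
8 4 0.368951046 0.0546519974 -1.46085042 0.5 6
9 5 0.353409192 0.0610674489 -0.460991785 0.5 8
10 4 1.20433446 -1.73051384 0.800856341 0.5 8
11 5 1.50007727 -0.787639166 0.954230203 0.5 10
12 4 -1.0138912 -3.01602095 -0.757009621 0.5 10
13 5 -0.702235564 -3.08453757 -1.70473122 0.5 12
14 4 -1.64621 -2.11661253 -3.54828844 0.5 12
15 5 -1.75926031 -2.98901396 -4.02382537 0.5 14
16 4 0.5999718 -0.223528133 -2.93927385 0.5 14
17 5 -0.0176374562 -0.197988051 -2.15320355 0.5 16
18 4 0.671470815 -0.294679202 0.0590299105 0.5 16
19 5 0.640542419 0.374175865 0.801779083 0.5 18
20 4 -1.23260276 -2.57639571 0.469241565 0.5 18
21 5 -0.394408945 -2.46361792 -0.0643428214 0.5 20
22 4 -1.97905445 -2.05703406 -2.38961719 0.5 20
23 5 -1.89519689 -2.42978932 -3.31374999 0.5 22
24 4 -0.655210388 0.253250344 -3.77165295 0.5 22
25 5 -1.58468224 -0.0432765272 -3.55221298 0.5 24
26 4 0.991975232 -0.507791192 -1.38259554 0.5 24
27 5 0.972508995 -0.461277613 -0.38386757 0.5 26
28 4 0.299538807 -2.43294085 0.81156275 0.5 26
29 5 1.17832514 -1.97107538 0.931624665 0.5 28
30 4 -2.12752391 -1.79317491 -0.831625031 0.5 28
31 5 -1.97227501 -2.03462263 -1.78953984 0.5 30
32 4 -1.92551453 -0.617740136 -3.58435918 0.5 30
33 5 -2.63327041 -1.16586607 -4.03004918 0.5 32
34 4 0.979926694 -0.858450002 -2.87692012 0.5 32
35 5 0.578348009 -0.424355211 -2.07051063 0.5 34
36 4 0.980910273 -1.06007182 0.116296825 0.5 34
37 5 1.44730922 -0.545935057 0.836113061 0.5 36
38 4 -1.99029071 -1.33544206 0.426354826 0.5 36
39 5 -1.33127486 -1.8356116 -0.13536445 0.5 38
40 4 -2.13575377 -0.535848406 -2.46146277 0.5 38
41 5 -2.3556813 -0.885335238 -3.37222665 0.5 40
42 4 0.47561784 0.179820289 -3.75318899 0.5 40
43 5 -0.385328153 0.621643558 -3.50106958 0.5 42
44 4 1.07808824 -1.44524016 -1.30447342 0.5 42
45 5 1.10975019 -1.36746337 -0.308005509 0.5 44
46 4 -0.836314261 -2.35251123 0.819655177 0.5 44
47 5 0.115707235 -2.64602964 0.906269375 0.5 46
48 4 -2.07675696 -0.23591568 -0.906996258 0.5 46
49 5 -2.13022812 -0.484921555 -1.87402103 0.5 48
50 4 -1.02953298 0.507983183 -3.61807287 0.5 48
51 5 -1.93221635 0.620482873 -4.03341195 0.5 50
52 4 0.843651342 -1.69271062 -2.81300933 0.5 50
53 5 0.864202011 -1.12917598 -1.98717255 0.5 52
54 4 0.631567217 -1.9079215 0.171735984 0.5 52
55 5 1.34860513 -1.87125887 0.867805294 0.5 54
56 4 -1.67548415 -0.0017207764 0.381289709 0.5 54
57 5 -1.5638383 -0.801943385 -0.207929248 0.5 56
58 4 -1.26990178 0.587310329 -2.53222111 0.5 56
59 5 -1.70192918 0.487901834 -3.42858615 0.5 58
60 4 1.12238989 -0.768066492 -3.73217706 0.5 58
61 5 0.826563982 0.14382109 -3.44766331 0.5 60
62 4 0.437727657 -2.2691271 -1.2265724 0.5 60
63 5 0.545832404 -2.22326355 -0.23349139 0.5 62
64 4 -1.62542071 -1.53840229 0.82512447 0.5 62
65 5 -1.15653893 -2.42006754 0.878193006 0.5 64
66 4 -1.02654964 0.779334036 -0.983038071 0.5 64
67 5 -1.21271202 0.65834548 -1.95807927 0.5 66
68 4 0.329680309 0.553059175 -3.64939139 0.5 66
69 5 -0.239100832 1.28013108 -4.03390986 0.5 68
70 4 0.107353463 -2.29954803 -2.74761375 0.5 68
71 5 0.498902755 -1.9337671 -1.90328357 0.5 70
72 4 -0.294964071 -2.3034734 0.225284695 0.5 70
73 5 0.256263358 -2.79863876 0.896819944 0.5 72
74 4 -0.586194249 0.680373915 0.334097175 0.5 72
75 5 -1.05934293 0.0506042353 -0.281955156 0.5 74
76 4 0.0200951579 0.793729116 -2.60181218 0.5 74
77 5 -0.381632685 1.04380377 -3.48276474 0.5 76
78 4 0.770201695 -1.89183793 -3.70864091 0.5 76
79 5 1.19916757 -1.04581112 -3.39205456 0.5 78
80 4 -0.694203608 -2.44288796 -1.14898059 0.5 78
81 5 -0.554299065 -2.4990473 -0.160409476 0.5 80
82 4 -1.67049672 -0.408547748 0.827964445 0.5 80
83 5 -1.96040217 -1.36540512 0.847427308 0.5 82
84 4 0.335419608 0.780214944 -1.05966448 0.5 82
85 5 0.150328555 0.819017545 -2.0416195 0.5 84
86 4 1.1889662 -0.409034654 -3.6782793 0.5 84
87 5 1.30013362 0.519860943 -4.03154235 0.5 86
88 4 -0.956577887 -2.25340182 -2.68080734 0.5 86
89 5 -0.449699318 -2.26941081 -1.81893854 0.5 88
90 4 -1.3158961 -1.90274273 0.276882405 0.5 88
91 5 -1.27321007 -2.66468068 0.9231242 0.5 90
92 4 0.58366068 0.419243672 0.284830591 0.5 90
93 5 -0.175006473 0.309619927 -0.357358466 0.5 92
94 4 1.01151014 0.127710747 -2.67015729 0.5 92
95 5 0.896429801 0.616914596 -3.53470117 0.5 94
96 4 -0.368553597 -2.3361012 -3.68260717 0.5 94
97 5 0.521662045 -2.04249848 -3.33430622 0.5 96
98 4 -1.71598389 -1.72943578 -1.07178572 0.5 96
99 5 -1.64333205 -1.89838595 -0.0888424091 0.5 98
100 4 -0.951560548 0.462781823 0.828171891 0.5 98
101 5 -1.83208051 -0.0110155513 0.81400707 0.5 100
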