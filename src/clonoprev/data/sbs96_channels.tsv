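index	channel
0	A[C>A]A
1	A[C>A]C
2	A[C>A]G
3	A[C>A]T
4	C[C>A]A
5	C[C>A]C
6	C[C>A]G
7	C[C>A]T
8	G[C>A]A
9	G[C>A]C
10	G[C>A]G
11	G[C>A]T
12	T[C>A]A
13	T[C>A]C
14	T[C>A]G
15	T[C>A]T
16	A[C>G]A
17	A[C>G]C
18	A[C>G]G
19	A[C>G]T
20	C[C>G]A
21	C[C>G]C
22	C[C>G]G
23	C[C>G]T
24	G[C>G]A
25	G[C>G]C
26	G[C>G]G
27	G[C>G]T
28	T[C>G]A
29	T[C>G]C
30	T[C>G]G
31	T[C>G]T
32	A[C>T]A
33	A[C>T]C
34	A[C>T]G
35	A[C>T]T
36	C[C>T]A
37	C[C>T]C
38	C[C>T]G
39	C[C>T]T
40	G[C>T]A
41	G[C>T]C
42	G[C>T]G
43	G[C>T]T
44	T[C>T]A
45	T[C>T]C
46	T[C>T]G
47	T[C>T]T
48	A[T>A]A
49	A[T>A]C
50	A[T>A]G
51	A[T>A]T
52	C[T>A]A
53	C[T>A]C
54	C[T>A]G
55	C[T>A]T
56	G[T>A]A
57	G[T>A]C
58	G[T>A]G
59	G[T>A]T
60	T[T>A]A
61	T[T>A]C
62	T[T>A]G
63	T[T>A]T
64	A[T>C]A
65	A[T>C]C
66	A[T>C]G
67	A[T>C]T
68	C[T>C]A
69	C[T>C]C
70	C[T>C]G
71	C[T>C]T
72	G[T>C]A
73	G[T>C]C
74	G[T>C]G
75	G[T>C]T
76	T[T>C]A
77	T[T>C]C
78	T[T>C]G
79	T[T>C]T
80	A[T>G]A
81	A[T>G]C
82	A[T>G]G
83	A[T>G]T
84	C[T>G]A
85	C[T>G]C
86	C[T>G]G
87	C[T>G]T
88	G[T>G]A
89	G[T>G]C
90	G[T>G]G
91	G[T>G]T
92	T[T>G]A
93	T[T>G]C
94	T[T>G]G
95	T[T>G]T
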