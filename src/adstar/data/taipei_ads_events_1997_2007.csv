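event_id,start_date,end_date
1,1997-01-01,1997-01-01
2,1997-03-07,1997-03-08
3,1997-03-30,1997-03-30
4,1997-04-08,1997-04-08
5,1997-04-21,1997-04-21
6,1997-04-27,1997-04-28
7,1998-01-04,1998-01-04
8,1998-02-13,1998-02-13
9,1998-02-18,1998-02-19
10,1998-03-07,1998-03-07
11,1998-03-19,1998-03-19
12,1998-03-30,1998-03-30
13,1998-04-04,1998-04-04
14,1998-04-15,1998-04-15
15,1998-04-17,1998-04-19
16,1998-04-24,1998-04-26
17,1998-05-01,1998-05-01
18,1998-11-05,1998-11-05
19,1998-12-15,1998-12-15
20,1999-01-27,1999-01-27
21,1999-02-19,1999-02-19
22,1999-03-08,1999-03-09
23,1999-03-26,1999-03-26
24,1999-04-07,1999-04-07
25,1999-04-13,1999-04-13
26,1999-11-25,1999-11-25
27,2000-03-06,2000-03-07
28,2000-03-24,2000-03-25
29,2000-03-28,2000-03-29
30,2000-04-06,2000-04-06
31,2000-04-08,2000-04-08
32,2000-04-10,2000-04-11
33,2000-04-15,2000-04-16
34,2000-04-22,2000-04-22
35,2000-04-27,2000-04-28
36,2000-05-01,2000-05-01
37,2000-05-03,2000-05-04
38,2000-05-13,2000-05-18
39,2000-12-24,2000-12-24
40,2001-01-13,2001-01-15
41,2001-02-01,2001-02-01
42,2001-02-16,2001-02-17
43,2001-02-21,2001-02-25
44,2001-03-01,2001-03-07
45,2001-04-12,2001-04-14
46,2001-05-01,2001-05-02
47,2002-02-11,2002-02-12
48,2002-03-06,2002-03-09
49,2002-03-23,2002-03-24
50,2002-03-31,2002-04-01
51,2002-04-08,2002-04-15
52,2002-04-17,2002-04-19
53,2003-02-18,2003-02-19
54,2003-02-23,2003-02-25
55,2003-03-06,2003-03-09
56,2003-03-25,2003-03-30
57,2003-04-25,2003-04-28
58,2004-01-01,2004-01-04
59,2004-01-13,2004-01-14
60,2004-01-21,2004-01-22
61,2004-01-24,2004-01-25
62,2004-02-06,2004-02-12
63,2004-02-14,2004-02-16
64,2004-02-26,2004-02-27
65,2004-03-03,2004-03-07
66,2004-04-02,2004-04-04
67,2005-03-18,2005-03-19
68,2005-11-29,2005-11-30
69,2005-12-21,2005-12-22
70,2006-03-19,2006-03-20
71,2006-03-29,2006-03-30
72,2006-04-20,2006-04-21
73,2007-01-28,2007-01-29
74,2007-04-02,2007-04-03
75,2007-04-17,2007-04-18
76,2007-12-30,2007-12-31
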