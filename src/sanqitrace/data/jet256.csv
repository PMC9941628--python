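index,r,g,b
0,0,0,128
1,0,0,132
2,0,0,136
3,0,0,140
4,0,0,144
5,0,0,147
6,0,0,152
7,0,0,156
8,0,0,160
9,0,0,163
10,0,0,168
11,0,0,172
12,0,0,176
13,0,0,179
14,0,0,184
15,0,0,188
16,0,0,192
17,0,0,195
18,0,0,200
19,0,0,204
20,0,0,208
21,0,0,211
22,0,0,216
23,0,0,220
24,0,0,224
25,0,0,227
26,0,0,232
27,0,0,236
28,0,0,240
29,0,0,243
30,0,0,248
31,0,0,252
32,0,0,255
33,0,4,255
34,0,8,255
35,0,13,255
36,0,16,255
37,0,21,255
38,0,25,255
39,0,29,255
40,0,32,255
41,0,36,255
42,0,40,255
43,0,45,255
44,0,48,255
45,0,53,255
46,0,57,255
47,0,61,255
48,0,64,255
49,0,68,255
50,0,72,255
51,0,77,255
52,0,80,255
53,0,85,255
54,0,89,255
55,0,93,255
56,0,96,255
57,0,100,255
58,0,104,255
59,0,109,255
60,0,112,255
61,0,117,255
62,0,121,255
63,0,125,255
64,0,128,255
65,0,132,255
66,0,137,255
67,0,140,255
68,0,144,255
69,0,148,255
70,0,153,255
71,0,156,255
72,0,160,255
73,0,164,255
74,0,169,255
75,0,172,255
76,0,176,255
77,0,180,255
78,0,185,255
79,0,188,255
80,0,192,255
81,0,196,255
82,0,201,255
83,0,204,255
84,0,208,255
85,0,212,255
86,0,217,255
87,0,220,255
88,0,224,255
89,0,228,255
90,0,233,255
91,0,236,255
92,0,240,255
93,0,244,255
94,0,249,255
95,0,252,255
96,1,255,254
97,5,255,250
98,10,255,245
99,14,255,242
100,17,255,238
101,21,255,234
102,26,255,229
103,30,255,226
104,33,255,222
105,37,255,218
106,42,255,213
107,46,255,210
108,49,255,206
109,53,255,202
110,58,255,197
111,62,255,194
112,66,255,190
113,69,255,186
114,74,255,181
115,78,255,178
116,82,255,174
117,85,255,170
118,90,255,165
119,94,255,162
120,98,255,158
121,101,255,154
122,106,255,149
123,110,255,146
124,114,255,142
125,117,255,138
126,122,255,133
127,126,255,130
128,130,255,126
129,133,255,122
130,137,255,118
131,141,255,114
132,146,255,109
133,150,255,105
134,154,255,101
135,158,255,98
136,162,255,94
137,165,255,90
138,169,255,86
139,173,255,82
140,178,255,77
141,182,255,73
142,186,255,69
143,190,255,66
144,194,255,62
145,197,255,58
146,201,255,54
147,205,255,50
148,210,255,45
149,214,255,41
150,218,255,37
151,222,255,33
152,226,255,30
153,229,255,26
154,233,255,22
155,237,255,18
156,242,255,13
157,246,255,9
158,250,255,5
159,254,255,1
160,255,252,0
161,255,249,0
162,255,245,0
163,255,241,0
164,255,236,0
165,255,232,0
166,255,228,0
167,255,224,0
168,255,220,0
169,255,217,0
170,255,213,0
171,255,209,0
172,255,204,0
173,255,200,0
174,255,196,0
175,255,192,0
176,255,188,0
177,255,185,0
178,255,181,0
179,255,177,0
180,255,172,0
181,255,168,0
182,255,164,0
183,255,160,0
184,255,156,0
185,255,153,0
186,255,149,0
187,255,145,0
188,255,140,0
189,255,136,0
190,255,132,0
191,255,128,0
192,255,125,0
193,255,121,0
194,255,117,0
195,255,113,0
196,255,108,0
197,255,104,0
198,255,100,0
199,255,96,0
200,255,93,0
201,255,89,0
202,255,85,0
203,255,81,0
204,255,76,0
205,255,72,0
206,255,68,0
207,255,64,0
208,255,61,0
209,255,57,0
210,255,53,0
211,255,49,0
212,255,44,0
213,255,40,0
214,255,36,0
215,255,32,0
216,255,29,0
217,255,25,0
218,255,21,0
219,255,17,0
220,255,12,0
221,255,8,0
222,255,4,0
223,255,0,0
224,252,0,0
225,248,0,0
226,244,0,0
227,240,0,0
228,235,0,0
229,231,0,0
230,227,0,0
231,224,0,0
232,220,0,0
233,216,0,0
234,212,0,0
235,208,0,0
236,203,0,0
237,199,0,0
238,195,0,0
239,192,0,0
240,188,0,0
241,184,0,0
242,180,0,0
243,176,0,0
244,171,0,0
245,167,0,0
246,163,0,0
247,160,0,0
248,156,0,0
249,152,0,0
250,148,0,0
251,144,0,0
252,139,0,0
253,135,0,0
254,132,0,0
255,128,0,0
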