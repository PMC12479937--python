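node_id	network
0	DMN
1	DMN
2	DMN
3	DMN
4	DMN
5	DMN
6	DMN
7	DMN
8	DMN
9	DMN
10	DMN
11	DMN
12	DMN
13	DMN
14	DMN
15	DMN
16	DMN
17	DMN
18	DMN
19	DMN
20	DMN
21	DMN
22	DMN
23	DMN
24	DMN
25	DMN
26	DMN
27	DMN
28	DMN
29	DMN
30	DMN
31	DMN
32	DMN
33	DMN
34	DMN
35	DMN
36	DMN
37	DMN
38	DMN
39	DMN
40	DMN
41	VIS
42	VIS
43	VIS
44	VIS
45	VIS
46	VIS
47	VIS
48	VIS
49	VIS
50	VIS
51	VIS
52	VIS
53	VIS
54	VIS
55	VIS
56	VIS
57	VIS
58	VIS
59	VIS
60	VIS
61	VIS
62	VIS
63	VIS
64	VIS
65	VIS
66	VIS
67	VIS
68	VIS
69	VIS
70	VIS
71	VIS
72	VIS
73	VIS
74	VIS
75	VIS
76	VIS
77	VIS
78	VIS
79	VIS
80	FPN
81	FPN
82	FPN
83	FPN
84	FPN
85	FPN
86	FPN
87	FPN
88	FPN
89	FPN
90	FPN
91	FPN
92	FPN
93	FPN
94	FPN
95	FPN
96	FPN
97	FPN
98	FPN
99	FPN
100	FPN
101	FPN
102	FPN
103	FPN
104	DAN
105	DAN
106	DAN
107	DAN
108	DAN
109	DAN
110	DAN
111	DAN
112	DAN
113	DAN
114	DAN
115	DAN
116	DAN
117	DAN
118	DAN
119	DAN
120	DAN
121	DAN
122	DAN
123	DAN
124	DAN
125	DAN
126	DAN
127	DAN
128	DAN
129	DAN
130	DAN
131	DAN
132	DAN
133	DAN
134	DAN
135	DAN
136	VAN
137	VAN
138	VAN
139	VAN
140	VAN
141	VAN
142	VAN
143	VAN
144	VAN
145	VAN
146	VAN
147	VAN
148	VAN
149	VAN
150	VAN
151	VAN
152	VAN
153	VAN
154	VAN
155	VAN
156	VAN
157	VAN
158	VAN
159	SAL
160	SAL
161	SAL
162	SAL
163	CON
164	CON
165	CON
166	CON
167	CON
168	CON
169	CON
170	CON
171	CON
172	CON
173	CON
174	CON
175	CON
176	CON
177	CON
178	CON
179	CON
180	CON
181	CON
182	CON
183	CON
184	CON
185	CON
186	CON
187	CON
188	CON
189	CON
190	CON
191	CON
192	CON
193	CON
194	CON
195	CON
196	CON
197	CON
198	CON
199	CON
200	CON
201	CON
202	CON
203	SMH
204	SMH
205	SMH
206	SMH
207	SMH
208	SMH
209	SMH
210	SMH
211	SMH
212	SMH
213	SMH
214	SMH
215	SMH
216	SMH
217	SMH
218	SMH
219	SMH
220	SMH
221	SMH
222	SMH
223	SMH
224	SMH
225	SMH
226	SMH
227	SMH
228	SMH
229	SMH
230	SMH
231	SMH
232	SMH
233	SMH
234	SMH
235	SMH
236	SMH
237	SMH
238	SMH
239	SMH
240	SMH
241	SMM
242	SMM
243	SMM
244	SMM
245	SMM
246	SMM
247	SMM
248	SMM
249	AUD
250	AUD
251	AUD
252	AUD
253	AUD
254	AUD
255	AUD
256	AUD
257	AUD
258	AUD
259	AUD
260	AUD
261	AUD
262	AUD
263	AUD
264	AUD
265	AUD
266	AUD
267	AUD
268	AUD
269	AUD
270	AUD
271	AUD
272	AUD
273	MEM
274	MEM
275	MEM
276	MEM
277	MEM
278	CTXT
279	CTXT
280	CTXT
281	CTXT
282	CTXT
283	CTXT
284	CTXT
285	CTXT
286	CTXT
287	CTXT
288	CTXT
289	CTXT
290	CTXT
291	CTXT
292	CTXT
293	CTXT
294	CTXT
295	CTXT
296	CTXT
297	CTXT
298	CTXT
299	CTXT
300	CTXT
301	CTXT
302	CTXT
303	CTXT
304	CTXT
305	CTXT
306	CTXT
307	CTXT
308	CTXT
309	CTXT
310	CTXT
311	CTXT
312	CTXT
313	CTXT
314	CTXT
315	CTXT
316	CTXT
317	CTXT
318	CTXT
319	CTXT
320	CTXT
321	CTXT
322	CTXT
323	CTXT
324	CTXT
325	ORBF
326	ORBF
327	ORBF
328	ORBF
329	ORBF
330	ORBF
331	ORBF
332	ORBF
333	SUBCORT
334	SUBCORT
335	SUBCORT
336	SUBCORT
337	SUBCORT
338	SUBCORT
339	SUBCORT
340	SUBCORT
341	SUBCORT
342	SUBCORT
343	SUBCORT
344	SUBCORT
345	SUBCORT
346	SUBCORT
347	SUBCORT
348	SUBCORT
349	SUBCORT
350	SUBCORT
351	SUBCORT
352	SUBCORT
353	SUBCORT
354	SUBCORT
355	SUBCORT
356	SUBCORT
357	SUBCORT
358	SUBCORT
359	SUBCORT
360	SUBCORT
361	SUBCORT
362	SUBCORT
363	SUBCORT
364	SUBCORT
365	SUBCORT
366	SUBCORT
367	SUBCORT
368	SUBCORT
369	SUBCORT
370	SUBCORT
371	SUBCORT
372	SUBCORT
373	SUBCORT
374	SUBCORT
375	SUBCORT
376	SUBCORT
377	SUBCORT
378	SUBCORT
379	SUBCORT
380	SUBCORT
381	SUBCORT
382	SUBCORT
383	SUBCORT
384	SUBCORT
385	SUBCORT
386	SUBCORT
387	SUBCORT
388	SUBCORT
389	SUBCORT
390	SUBCORT
391	SUBCORT
392	SUBCORT
393	SUBCORT
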