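x	y	z	label	network
23	-14	26	vPFC	cingulo-opercular
-12	8	19	dACC	cingulo-opercular
-19	11	4	anterior insula	cingulo-opercular
-37	-13	-1	frontal	cingulo-opercular
-29	7	44	aPFC	cingulo-opercular
-41	7	27	anterior insula	cingulo-opercular
24	-6	3	vPFC	cingulo-opercular
-4	-12	42	aPFC	cingulo-opercular
10	35	13	thalamus	cingulo-opercular
37	-22	8	basal ganglia	cingulo-opercular
44	17	30	frontal	cingulo-opercular
11	30	12	basal ganglia	cingulo-opercular
10	-1	21	mFC	cingulo-opercular
-22	40	4	aPFC	cingulo-opercular
35	16	44	temporal	cingulo-opercular
-14	7	19	dACC	cingulo-opercular
24	33	-4	basal ganglia	cingulo-opercular
-13	43	-5	anterior insula	cingulo-opercular
42	30	6	mFC	cingulo-opercular
-30	10	26	aPFC	cingulo-opercular
-25	-17	13	aPFC	cingulo-opercular
2	-4	16	thalamus	cingulo-opercular
33	29	40	aPFC	cingulo-opercular
13	-2	-5	dACC	cingulo-opercular
10	31	31	vPFC	cingulo-opercular
-41	-23	43	dACC	cingulo-opercular
-19	20	1	anterior insula	cingulo-opercular
-13	1	2	vPFC	cingulo-opercular
45	29	34	temporal	cingulo-opercular
-43	37	44	frontal	cingulo-opercular
-7	-3	11	vPFC	cingulo-opercular
29	40	12	vPFC	cingulo-opercular
14	24	47	dlPFC	fronto-parietal
25	-33	27	dlPFC	fronto-parietal
-19	33	20	dlPFC	fronto-parietal
45	-44	23	dlPFC	fronto-parietal
-28	-15	32	vlPFC	fronto-parietal
20	-53	24	frontal	fronto-parietal
-33	-56	38	IPL	fronto-parietal
45	-45	55	frontal	fronto-parietal
41	-59	21	precuneus	fronto-parietal
-19	-17	34	frontal	fronto-parietal
-48	35	33	dFC	fronto-parietal
48	-10	40	IPS	fronto-parietal
-18	-51	24	frontal	fronto-parietal
-18	33	47	precuneus	fronto-parietal
-38	-8	21	dFC	fronto-parietal
-3	-5	46	IPS	fronto-parietal
-38	-48	40	dlPFC	fronto-parietal
31	42	44	dlPFC	fronto-parietal
-48	-53	28	IPS	fronto-parietal
22	-40	52	precuneus	fronto-parietal
26	50	30	precuneus	fronto-parietal
-32	52	8	vmPFC	default-mode
50	-51	46	angular gyrus	default-mode
-47	-20	8	parahippocampal	default-mode
-33	-70	-7	aPFC	default-mode
-18	30	17	post cingulate	default-mode
24	-50	43	aPFC	default-mode
-28	-18	-1	sup frontal	default-mode
48	-69	-15	occipital	default-mode
-27	35	44	aPFC	default-mode
11	35	6	parahippocampal	default-mode
-7	-69	33	angular gyrus	default-mode
-41	4	-6	inf temporal	default-mode
23	7	45	aPFC	default-mode
27	46	13	sup frontal	default-mode
19	22	35	post cingulate	default-mode
49	40	12	occipital	default-mode
-42	-38	22	aPFC	default-mode
10	-7	31	inf temporal	default-mode
-36	26	-2	aPFC	default-mode
39	-55	36	aPFC	default-mode
8	30	30	post cingulate	default-mode
-25	23	21	parahippocampal	default-mode
33	31	-9	occipital	default-mode
13	-12	29	aPFC	default-mode
3	-17	47	aPFC	default-mode
-46	-21	14	parahippocampal	default-mode
-18	17	44	post cingulate	default-mode
23	5	6	precuneus	default-mode
-40	42	37	aPFC	default-mode
-12	52	16	aPFC	default-mode
-24	-3	24	precuneus	default-mode
-42	6	3	aPFC	default-mode
1	36	33	post cingulate	default-mode
-40	-31	23	precuneus	default-mode
-24	-60	6	temporal	occipital
38	-96	-8	fusiform	occipital
-24	-89	-13	fusiform	occipital
39	-93	-8	occipital	occipital
-35	-56	-14	temporal	occipital
-19	-95	-9	fusiform	occipital
3	-78	28	occipital	occipital
-31	-67	-12	temporal	occipital
8	-78	14	temporal	occipital
-2	-74	12	temporal	occipital
-6	-56	8	fusiform	occipital
-5	-96	-2	post occipital	occipital
8	-84	29	fusiform	occipital
-3	-89	21	fusiform	occipital
27	-70	-14	post occipital	occipital
23	-60	9	temporal	occipital
-39	-73	2	occipital	occipital
-25	-91	-3	temporal	occipital
-37	-71	13	post occipital	occipital
-4	-69	24	post occipital	occipital
17	-80	17	occipital	occipital
40	-78	20	temporal	occipital
58	11	14	frontal	sensorimotor
60	8	34	dFC	sensorimotor
-55	7	23	vFC	sensorimotor
10	5	51	pre-SMA	sensorimotor
43	1	12	vFC	sensorimotor
0	-1	52	SMA	sensorimotor
53	-3	32	frontal	sensorimotor
58	-3	17	precentral gyrus	sensorimotor
-42	-3	11	mid-insula	sensorimotor
-44	-6	49	precentral gyrus	sensorimotor
-26	-8	54	parietal	sensorimotor
46	-8	24	precentral gyrus	sensorimotor
-54	-9	23	precentral gyrus	sensorimotor
44	-11	38	precentral gyrus	sensorimotor
-47	-12	36	parietal	sensorimotor
33	-12	16	mid-insula	sensorimotor
-36	-12	15	mid-insula	sensorimotor
59	-13	8	temporal	sensorimotor
-38	-15	59	parietal	sensorimotor
-47	-18	50	parietal	sensorimotor
46	-20	45	parietal	sensorimotor
-55	-22	38	parietal	sensorimotor
-54	-22	22	precentral gyrus	sensorimotor
-54	-22	9	temporal	sensorimotor
41	-23	55	parietal	sensorimotor
42	-24	17	posterior insula	sensorimotor
18	-27	62	parietal	sensorimotor
-38	-27	60	parietal	sensorimotor
-24	-30	64	parietal	sensorimotor
-41	-31	48	posterior parietal	sensorimotor
-41	-37	16	temporal	sensorimotor
-53	-37	13	temporal	sensorimotor
34	-39	65	superior parietal	sensorimotor
-28	-44	-25	lateral cerebellum	cerebellum
-24	-54	-21	lateral cerebellum	cerebellum
-37	-54	-37	inferior cerebellum	cerebellum
-34	-57	-24	lateral cerebellum	cerebellum
-6	-60	-15	medial cerebellum	cerebellum
-25	-60	-34	inferior cerebellum	cerebellum
32	-61	-31	inferior cerebellum	cerebellum
-16	-64	-21	medial cerebellum	cerebellum
21	-64	-22	lateral cerebellum	cerebellum
1	-66	-24	medial cerebellum	cerebellum
-34	-67	-29	inferior cerebellum	cerebellum
-11	-72	-14	medial cerebellum	cerebellum
33	-73	-30	inferior cerebellum	cerebellum
5	-75	-11	medial cerebellum	cerebellum
14	-75	-21	medial cerebellum	cerebellum
-21	-79	-33	inferior cerebellum	cerebellum
-6	-79	-33	inferior cerebellum	cerebellum
18	-81	-33	inferior cerebellum	cerebellum
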