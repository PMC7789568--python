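sample_id	age	father_age_collection	father_age_pregnancy	collection_date	group	volume	concentration	total_spermatozoa	progressive_pct	non_progressive_pct	immotile_pct	total_motile
IVI 1	42	42	31	7/27/15	case	2.2	83	182.6	58	11	31	105.91
IVI 2	44	45	43	7/28/15	case	1.5	38	57	42	11	47	23.94
IVI 3	41	41	38	7/29/15	case	3	68	204	44	11	45	89.76
IVI 4	38	38	34	7/29/15	case	3.4	66	224.4	35	11	54	78.54
IVI 5	37	37	33	7/30/15	case	1.4	10	14	50	14	36	7
IVI 6	39	49	40	8/4/15	case	2.2	23	50.6	31	26	43	15.69
IVI 7	41	41	31	8/12/15	case	6	47	282	69	14	17	194.58
IVI 8	42	42	32	8/14/15	case	2.5	91	227.5	60	15	25	136.5
IVI 9	45	45	35	9/9/15	case	3.5	87	304.5	50	13	37	152.25
IVI 10		39	31	9/28/15	case	3	33.3	99.9	44	9	47	43.96
IVI 11		45	39	12/21/15	case	4	120	480	50	12	38	240
IVI 12	35	37	24	9/5/17	case	5.4	36.3	196.02	43	3	54	84.29
IVI 13	46	46	35	3/7/16	case	4.2	17.6	73.92	60	17	23	44.35
IVI 14	40	40	36	10/11/16	control	2.8	141.65	396.62	55	10	35	218.14
IVI 15	41	41	36	10/11/16	control	1	34.3	34.3	31	18	51	10.63
IVI 16	46	46	35	10/17/16	control	2.2	5.5	12.1	29	3	68	3.51
IVI 17	44	44	33	10/20/16	control	4.8	10.5	50.4	42	12	46	21.17
IVI 18	38	38	31	10/21/16	control	3.2	1.6	5.12	28	13	59	1.43
IVI 19	36	36	34	11/3/16	control	6.8	14	95.2	32	3	65	30.46
IVI 20	41	41	41	3/22/17	control	2.2	91.8	201.96	49	14	37	98.96
IVI 21	42	42	32	5/23/17	control	1.4	42.1	58.94	37	23	40	21.81
IVI 22	37	37	29	9/6/17	control	4.2	54	226.8	52	9	39	117.94
IVI 23	43	43	36	9/6/17	control	1.8	13	23.4	23	20	57	5.38
IVI 24	54	54	27	9/15/17	control	2.5	52	130	48	7	45	62.4
IVI 25	38	38	34	9/15/17	control	5.5	1.7	9.35	11	8	81	1.03
IVI 26	43	43	33	9/22/17	control	1.5	96	144	35	17	48	50.4
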