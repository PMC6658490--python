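state	residue	d-8	d-7	d-6	d-5	d-4	d-3	d-2	d-1	d+0	d+1	d+2	d+3	d+4	d+5	d+6	d+7	d+8
helix	A	4	8	12	16	19	23	27	31	35	31	27	23	19	16	12	8	4
helix	C	-2	-3	-5	-7	-8	-10	-12	-13	-15	-13	-12	-10	-8	-7	-5	-3	-2
helix	D	1	1	2	2	3	3	4	4	5	4	4	3	3	2	2	1	1
helix	E	4	9	13	18	22	27	31	36	40	36	31	27	22	18	13	9	4
helix	F	1	2	3	4	6	7	8	9	10	9	8	7	6	4	3	2	1
helix	G	-4	-9	-13	-18	-22	-27	-31	-36	-40	-36	-31	-27	-22	-18	-13	-9	-4
helix	H	1	2	3	4	6	7	8	9	10	9	8	7	6	4	3	2	1
helix	I	1	1	2	2	3	3	4	4	5	4	4	3	3	2	2	1	1
helix	K	2	3	5	7	8	10	12	13	15	13	12	10	8	7	5	3	2
helix	L	3	7	10	13	17	20	23	27	30	27	23	20	17	13	10	7	3
helix	M	3	6	8	11	14	17	19	22	25	22	19	17	14	11	8	6	3
helix	N	-2	-4	-7	-9	-11	-13	-16	-18	-20	-18	-16	-13	-11	-9	-7	-4	-2
helix	P	-7	-13	-20	-27	-33	-40	-47	-53	-60	-53	-47	-40	-33	-27	-20	-13	-7
helix	Q	2	4	7	9	11	13	16	18	20	18	16	13	11	9	7	4	2
helix	R	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
helix	S	-2	-3	-5	-7	-8	-10	-12	-13	-15	-13	-12	-10	-8	-7	-5	-3	-2
helix	T	-1	-2	-3	-4	-6	-7	-8	-9	-10	-9	-8	-7	-6	-4	-3	-2	-1
helix	V	-1	-1	-2	-2	-3	-3	-4	-4	-5	-4	-4	-3	-3	-2	-2	-1	-1
helix	W	1	1	2	2	3	3	4	4	5	4	4	3	3	2	2	1	1
helix	Y	-2	-4	-7	-9	-11	-13	-16	-18	-20	-18	-16	-13	-11	-9	-7	-4	-2
sheet	A	-1	-2	-3	-4	-6	-7	-8	-9	-10	-9	-8	-7	-6	-4	-3	-2	-1
sheet	C	3	6	8	11	14	17	19	22	25	22	19	17	14	11	8	6	3
sheet	D	-3	-7	-10	-13	-17	-20	-23	-27	-30	-27	-23	-20	-17	-13	-10	-7	-3
sheet	E	-3	-7	-10	-13	-17	-20	-23	-27	-30	-27	-23	-20	-17	-13	-10	-7	-3
sheet	F	3	6	8	11	14	17	19	22	25	22	19	17	14	11	8	6	3
sheet	G	-2	-4	-7	-9	-11	-13	-16	-18	-20	-18	-16	-13	-11	-9	-7	-4	-2
sheet	H	-1	-2	-3	-4	-6	-7	-8	-9	-10	-9	-8	-7	-6	-4	-3	-2	-1
sheet	I	4	9	13	18	22	27	31	36	40	36	31	27	22	18	13	9	4
sheet	K	-2	-3	-5	-7	-8	-10	-12	-13	-15	-13	-12	-10	-8	-7	-5	-3	-2
sheet	L	2	3	5	7	8	10	12	13	15	13	12	10	8	7	5	3	2
sheet	M	1	2	3	4	6	7	8	9	10	9	8	7	6	4	3	2	1
sheet	N	-2	-4	-7	-9	-11	-13	-16	-18	-20	-18	-16	-13	-11	-9	-7	-4	-2
sheet	P	-4	-9	-13	-18	-22	-27	-31	-36	-40	-36	-31	-27	-22	-18	-13	-9	-4
sheet	Q	-1	-2	-3	-4	-6	-7	-8	-9	-10	-9	-8	-7	-6	-4	-3	-2	-1
sheet	R	-1	-1	-2	-2	-3	-3	-4	-4	-5	-4	-4	-3	-3	-2	-2	-1	-1
sheet	S	-2	-3	-5	-7	-8	-10	-12	-13	-15	-13	-12	-10	-8	-7	-5	-3	-2
sheet	T	2	3	5	7	8	10	12	13	15	13	12	10	8	7	5	3	2
sheet	V	4	9	13	18	22	27	31	36	40	36	31	27	22	18	13	9	4
sheet	W	3	6	8	11	14	17	19	22	25	22	19	17	14	11	8	6	3
sheet	Y	3	7	10	13	17	20	23	27	30	27	23	20	17	13	10	7	3
turn	A	0	0	0	0	-6	-12	-18	-24	-30	-24	-18	-12	-6	0	0	0	0
turn	C	0	0	0	0	2	4	6	8	10	8	6	4	2	0	0	0	0
turn	D	0	0	0	0	6	12	18	24	30	24	18	12	6	0	0	0	0
turn	E	0	0	0	0	-4	-8	-12	-16	-20	-16	-12	-8	-4	0	0	0	0
turn	F	0	0	0	0	-5	-10	-15	-20	-25	-20	-15	-10	-5	0	0	0	0
turn	G	0	0	0	0	8	16	24	32	40	32	24	16	8	0	0	0	0
turn	H	0	0	0	0	-2	-4	-6	-8	-10	-8	-6	-4	-2	0	0	0	0
turn	I	0	0	0	0	-8	-16	-24	-32	-40	-32	-24	-16	-8	0	0	0	0
turn	K	0	0	0	0	1	2	3	4	5	4	3	2	1	0	0	0	0
turn	L	0	0	0	0	-7	-14	-21	-28	-35	-28	-21	-14	-7	0	0	0	0
turn	M	0	0	0	0	-5	-10	-15	-20	-25	-20	-15	-10	-5	0	0	0	0
turn	N	0	0	0	0	7	14	21	28	35	28	21	14	7	0	0	0	0
turn	P	0	0	0	0	9	18	27	36	45	36	27	18	9	0	0	0	0
turn	Q	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
turn	R	0	0	0	0	-1	-2	-3	-4	-5	-4	-3	-2	-1	0	0	0	0
turn	S	0	0	0	0	5	10	15	20	25	20	15	10	5	0	0	0	0
turn	T	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
turn	V	0	0	0	0	-8	-16	-24	-32	-40	-32	-24	-16	-8	0	0	0	0
turn	W	0	0	0	0	-1	-2	-3	-4	-5	-4	-3	-2	-1	0	0	0	0
turn	Y	0	0	0	0	2	4	6	8	10	8	6	4	2	0	0	0	0
coil	A	0	0	0	0	-1	-2	-3	-4	-5	-4	-3	-2	-1	0	0	0	0
coil	C	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
coil	D	0	0	0	0	2	4	6	8	10	8	6	4	2	0	0	0	0
coil	E	0	0	0	0	-2	-4	-6	-8	-10	-8	-6	-4	-2	0	0	0	0
coil	F	0	0	0	0	-3	-6	-9	-12	-15	-12	-9	-6	-3	0	0	0	0
coil	G	0	0	0	0	4	8	12	16	20	16	12	8	4	0	0	0	0
coil	H	0	0	0	0	-1	-2	-3	-4	-5	-4	-3	-2	-1	0	0	0	0
coil	I	0	0	0	0	-4	-8	-12	-16	-20	-16	-12	-8	-4	0	0	0	0
coil	K	0	0	0	0	1	2	3	4	5	4	3	2	1	0	0	0	0
coil	L	0	0	0	0	-4	-8	-12	-16	-20	-16	-12	-8	-4	0	0	0	0
coil	M	0	0	0	0	-3	-6	-9	-12	-15	-12	-9	-6	-3	0	0	0	0
coil	N	0	0	0	0	2	4	6	8	10	8	6	4	2	0	0	0	0
coil	P	0	0	0	0	5	10	15	20	25	20	15	10	5	0	0	0	0
coil	Q	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
coil	R	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
coil	S	0	0	0	0	3	6	9	12	15	12	9	6	3	0	0	0	0
coil	T	0	0	0	0	2	4	6	8	10	8	6	4	2	0	0	0	0
coil	V	0	0	0	0	-3	-6	-9	-12	-15	-12	-9	-6	-3	0	0	0	0
coil	W	0	0	0	0	-2	-4	-6	-8	-10	-8	-6	-4	-2	0	0	0	0
coil	Y	0	0	0	0	-1	-2	-3	-4	-5	-4	-3	-2	-1	0	0	0	0
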