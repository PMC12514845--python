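halogen	acceptor_class	parameter	n	mean	median	q1	q3	mad
F	O-C	distance	4381	3.5	3.5	3.35	3.65	0.15
F	O-C	theta1	4381	132	132	114	150	18.0
F	O-C	theta2	4381	105	105	92	120	14.0
F	S-C	distance	554	3.75	3.75	3.6	3.9	0.15
F	S-C	theta1	554	132	132	114	150	18.0
F	S-C	theta2	554	105	105	92	120	14.0
Cl	O-C	distance	456	3.5	3.5	3.34	3.64	0.15
Cl	O-C	theta1	456	143	143	125	158	16.5
Cl	O-C	theta2	456	108	108	95	121	13.0
Cl	S-C	distance	80	3.72	3.72	3.56	3.88	0.16
Cl	S-C	theta1	80	143	143	125	158	16.5
Cl	S-C	theta2	80	108	108	95	121	13.0
Br	O-C	distance	2479	3.45	3.45	3.28	3.6	0.16
Br	O-C	theta1	2479	154	154	139	166	13.5
Br	O-C	theta2	2479	112	112	98	124	13.0
Br	S-C	distance	312	3.7	3.7	3.52	3.86	0.17
Br	S-C	theta1	312	154	154	139	166	13.5
Br	S-C	theta2	312	112	112	98	124	13.0
I	O-C	distance	156	3.4	3.4	3.15	3.62	0.235
I	O-C	theta1	156	169	169	158	175	8.5
I	O-C	theta2	156	120	120	105	132	13.5
I	S-C	distance	5	3.6	3.6	3.35	3.82	0.235
I	S-C	theta1	5	169	169	158	175	8.5
I	S-C	theta2	5	120	120	105	132	13.5
F	Phe	distance	2097	4.8	4.8	4.45	5.15	0.35
F	Phe	theta1	2097	127	127	110	143	16.5
F	Tyr	distance	1328	4.8	4.8	4.45	5.15	0.35
F	Tyr	theta1	1328	127	127	110	143	16.5
F	His	distance	1135	4.8	4.8	4.45	5.15	0.35
F	His	theta1	1135	127	127	110	143	16.5
F	Trp	distance	539	4.8	4.8	4.45	5.15	0.35
F	Trp	theta1	539	127	127	110	143	16.5
Cl	Phe	distance	167	4.8	4.8	4.45	5.15	0.35
Cl	Phe	theta1	167	127	127	110	143	16.5
Cl	Tyr	distance	102	4.8	4.8	4.45	5.15	0.35
Cl	Tyr	theta1	102	127	127	110	143	16.5
Cl	His	distance	55	4.8	4.8	4.45	5.15	0.35
Cl	His	theta1	55	118	118	102	134	16.0
Cl	Trp	distance	121	4.8	4.8	4.45	5.15	0.35
Cl	Trp	theta1	121	118	118	102	134	16.0
Br	Phe	distance	1100	4.8	4.8	4.45	5.15	0.35
Br	Phe	theta1	1100	127	127	110	143	16.5
Br	Tyr	distance	895	4.8	4.8	4.45	5.15	0.35
Br	Tyr	theta1	895	127	127	110	143	16.5
Br	His	distance	257	4.8	4.8	4.45	5.15	0.35
Br	His	theta1	257	118	118	102	134	16.0
Br	Trp	distance	225	4.8	4.8	4.45	5.15	0.35
Br	Trp	theta1	225	118	118	102	134	16.0
I	Phe	distance	49	5.1	5.1	4.75	5.45	0.35
I	Phe	theta1	49	127	127	110	143	16.5
I	Tyr	distance	14	5.1	5.1	4.75	5.45	0.35
I	Tyr	theta1	14	127	127	110	143	16.5
I	His	distance	9	5.1	5.1	4.75	5.45	0.35
I	His	theta1	9	127	127	110	143	16.5
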