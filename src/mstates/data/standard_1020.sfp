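Fp1	-0.309017	0.951057	0.000000
Fp2	0.309017	0.951057	0.000000
F7	-0.809017	0.587785	0.000000
F3	-0.433013	0.750000	0.500000
Fz	0.000000	0.707107	0.707107
F4	0.433013	0.750000	0.500000
F8	0.809017	0.587785	0.000000
T3	-1.000000	0.000000	0.000000
C3	-0.707107	0.000000	0.707107
Cz	0.000000	0.000000	1.000000
C4	0.707107	0.000000	0.707107
T4	1.000000	0.000000	0.000000
T5	-0.809017	-0.587785	0.000000
P3	-0.433013	-0.750000	0.500000
Pz	0.000000	-0.707107	0.707107
P4	0.433013	-0.750000	0.500000
T6	0.809017	-0.587785	0.000000
O1	-0.309017	-0.951057	0.000000
O2	0.309017	-0.951057	0.000000
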