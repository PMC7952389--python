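term	neighbor	central	n15	h1	n15_sd	h1_sd
intrinsic	-	GC	149.92	14.01	0.11	0.06
intrinsic	-	UA	164.03	14.85	0.12	0.06
intrinsic	-	GU	146.15	12.20	0.13	0.05
intrinsic	-	UG	159.69	12.27	0.16	0.07
5p	GC	GC	-0.25	-0.36
5p	GC	UA	-0.37	-0.24
5p	GC	GU	-0.32	-0.38
5p	GC	UG	-0.30	-0.10
5p	UA	GC	-1.29	-1.04
5p	UA	UA	-0.25	-0.78
5p	UA	GU	-1.38	-0.97
5p	UA	UG	-0.73	-0.29
5p	GU	GC	-0.37	-0.22
5p	GU	UA	-0.08	-0.26
5p	GU	GU	-0.27	-0.18
5p	GU	UG	-0.10	-0.07
5p	UG	GC	-1.02	-0.71
5p	UG	UA	-0.24	-0.36
5p	UG	GU	-1.59	-0.81
5p	UG	UG	-0.88	0.05
5p	AU	GC	-0.49	-0.20
5p	AU	UA	-0.59	-0.47
5p	AU	GU	-0.55	-0.28
5p	AU	UG	-0.79	-0.32
5p	CG	GC	-1.16	-0.72
5p	CG	UA	-0.58	-0.54
5p	CG	GU	-1.06	-0.88
5p	CG	UG	-1.03	-0.20
3p	GC	GC	-1.69	-0.77
3p	GC	UA	-1.10	-0.69
3p	GC	GU	-2.08	-0.75
3p	GC	UG	-0.01	-0.20
3p	UA	GC	-0.97	-0.19
3p	UA	UA	-0.81	-0.10
3p	UA	GU	-0.63	-0.05
3p	UA	UG	-0.24	-0.04
3p	GU	GC	-1.15	-0.77
3p	GU	UA	-0.69	-0.49
3p	GU	GU	-2.09	-0.88
3p	GU	UG	0.13	0.01
3p	UG	GC	-0.75	-0.07
3p	UG	UA	-1.27	-0.14
3p	UG	GU	-0.51	-0.18
3p	UG	UG	-0.73	-0.07
3p	AU	GC	-2.18	-1.05
3p	AU	UA	-1.48	-0.87
3p	AU	GU	-2.62	-1.07
3p	AU	UG	-0.36	-0.23
3p	CG	GC	-0.77	-0.21
3p	CG	UA	-0.53	-0.02
3p	CG	GU	-0.25	-0.14
3p	CG	UG	-0.18	0.17
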