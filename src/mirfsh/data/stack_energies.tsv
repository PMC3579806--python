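# Simplified nearest-neighbor RNA:RNA duplex parameters (kcal/mol).
# A base pair is written <strand1 base><strand2 base>; "stack" rows give the
# free energy of two adjacent pairs (5'-side pair, 3'-side pair on strand 1).
# Tiers: both pairs G:C -3.3; G:C next to A:U -2.2; both A:U -1.1;
# any stack containing one wobble -1.0; two wobbles -0.4.
param	duplex_init	4.1
param	loop_open	3.0
param	loop_per_nt	0.5
stack	AU	AU	-1.1
stack	AU	UA	-1.1
stack	AU	CG	-2.2
stack	AU	GC	-2.2
stack	AU	GU	-1.0
stack	AU	UG	-1.0
stack	UA	AU	-1.1
stack	UA	UA	-1.1
stack	UA	CG	-2.2
stack	UA	GC	-2.2
stack	UA	GU	-1.0
stack	UA	UG	-1.0
stack	CG	AU	-2.2
stack	CG	UA	-2.2
stack	CG	CG	-3.3
stack	CG	GC	-3.3
stack	CG	GU	-1.0
stack	CG	UG	-1.0
stack	GC	AU	-2.2
stack	GC	UA	-2.2
stack	GC	CG	-3.3
stack	GC	GC	-3.3
stack	GC	GU	-1.0
stack	GC	UG	-1.0
stack	GU	AU	-1.0
stack	GU	UA	-1.0
stack	GU	CG	-1.0
stack	GU	GC	-1.0
stack	GU	GU	-0.4
stack	GU	UG	-0.4
stack	UG	AU	-1.0
stack	UG	UA	-1.0
stack	UG	CG	-1.0
stack	UG	GC	-1.0
stack	UG	GU	-0.4
stack	UG	UG	-0.4
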