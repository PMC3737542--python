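# mirsite nearest-neighbor energy parameters, version 1
# Units: kcal/mol at 37 C (310.15 K).
# stack <5'pair> <3'pair> <dG>
#   A pair is written <top base><bottom base>; the step
#   "stack XY WZ" is the helix 5'-X W-3' / 3'-Y Z-5'.
#   Watson-Crick/Watson-Crick steps use published Turner 2004 values;
#   wobble-containing steps use Turner-style magnitudes.
# scalar <name> <value>
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	UA	UA	-0.93
stack	GC	GC	-3.26
stack	GC	CG	-3.42
stack	CG	GC	-2.36
stack	CG	CG	-3.26
stack	GC	AU	-2.35
stack	UA	CG	-2.35
stack	GC	UA	-2.24
stack	AU	CG	-2.24
stack	CG	AU	-2.11
stack	UA	GC	-2.11
stack	CG	UA	-2.08
stack	AU	GC	-2.08
stack	AU	GU	-0.55
stack	UG	UA	-0.55
stack	AU	UG	-1.36
stack	GU	UA	-1.36
stack	UA	GU	-1.27
stack	UG	AU	-1.27
stack	UA	UG	-1.41
stack	GU	AU	-1.41
stack	CG	GU	-1.41
stack	UG	GC	-1.41
stack	CG	UG	-2.11
stack	GU	GC	-2.11
stack	GC	GU	-1.53
stack	UG	CG	-1.53
stack	GC	UG	-2.51
stack	GU	CG	-2.51
stack	GU	GU	-0.50
stack	UG	UG	-0.50
stack	GU	UG	0.47
stack	UG	GU	-0.60
scalar	duplex_init	4.09
scalar	bulge_per_nt	1.8
scalar	internal_per_nt	1.1
scalar	max_loop	15
scalar	pair_penalty	1.1
scalar	min_hairpin	3
scalar	rt	0.6163
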