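kind	key	value
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	UA/AU	-1.33
stack	CU/GA	-2.08
stack	CA/GU	-2.11
stack	GU/CA	-2.24
stack	GA/CU	-2.35
stack	CG/GC	-2.36
stack	GG/CC	-3.26
stack	GC/CG	-3.42
gu_stack	GU_GC	-1.40
gu_stack	GU_AU	-0.90
gu_stack	GU_GU	-0.50
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
internal	2	1.5
internal	3	1.8
internal	4	2.0
internal	5	2.2
internal	6	2.5
param	ln_extrapolation	1.08
param	min_loop	3
param	duplex_mismatch	1.10
param	duplex_bulge_nt	2.00
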