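# Nearest-neighbor RNA:RNA duplex parameters, version 1 (kcal/mol, 37 C).
# Stack rows: kind=stack, key = 5'-side pair + 3'-side pair written as
# top-strand base + bottom-strand base (antiparallel); value = dG37.
# Watson-Crick stack free energies follow the published Turner-style
# nearest-neighbor set; G-U wobble stacks likewise, with the two
# destabilizing (positive) GU/UG motifs clamped to 0 so that every
# tabulated stack is stabilizing or neutral.
# Loop rows: kind=bulge|internal, key = total unpaired bases; value = dG37.
# kind=init: duplex initiation penalty.  kind=max_loop: per-side cap on
# unpaired bases between consecutive pairs (model definition).
kind	key	value
init	-	4.09
max_loop	-	8
stack	AU,AU	-0.93
stack	AU,CG	-2.24
stack	AU,GC	-2.08
stack	AU,UA	-1.10
stack	CG,AU	-2.11
stack	CG,CG	-3.26
stack	CG,GC	-2.36
stack	CG,UA	-2.08
stack	GC,AU	-2.35
stack	GC,CG	-3.42
stack	GC,GC	-3.26
stack	GC,UA	-2.24
stack	UA,AU	-1.33
stack	UA,CG	-2.35
stack	UA,GC	-2.11
stack	UA,UA	-0.93
stack	AU,GU	-1.36
stack	UG,UA	-1.36
stack	AU,UG	-0.55
stack	GU,UA	-0.55
stack	CG,GU	-2.11
stack	UG,GC	-2.11
stack	CG,UG	-1.41
stack	GU,GC	-1.41
stack	GC,GU	-2.51
stack	UG,CG	-2.51
stack	GC,UG	-1.53
stack	GU,CG	-1.53
stack	UA,GU	-1.00
stack	UG,AU	-1.00
stack	UA,UG	-1.27
stack	GU,AU	-1.27
stack	GU,GU	-0.50
stack	UG,UG	-0.50
stack	GU,UG	0.00
stack	UG,GU	0.00
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
bulge	7	4.70
bulge	8	5.00
internal	2	1.50
internal	3	1.60
internal	4	1.70
internal	5	1.80
internal	6	2.00
internal	7	2.20
internal	8	2.30
internal	9	2.40
internal	10	2.50
internal	11	2.60
internal	12	2.70
internal	13	2.80
internal	14	2.90
internal	15	3.00
internal	16	3.10
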