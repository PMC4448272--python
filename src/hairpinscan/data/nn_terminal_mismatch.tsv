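# First/last mismatch of an internal loop: dG_m(closing, x, y) kcal/mol.
# x = strand-1 mismatch base, y = strand-2 mismatch base.
closing	x	y	dg
AU	A	A	-0.80
AU	A	C	-0.80
AU	A	G	-1.10
AU	A	U	-0.80
AU	C	A	-0.80
AU	C	C	-0.80
AU	C	G	-0.80
AU	C	U	-0.80
AU	G	A	-1.10
AU	G	C	-0.80
AU	G	G	-1.10
AU	G	U	-0.80
AU	U	A	-0.80
AU	U	C	-0.80
AU	U	G	-0.80
AU	U	U	-1.00
UA	A	A	-0.80
UA	A	C	-0.80
UA	A	G	-1.10
UA	A	U	-0.80
UA	C	A	-0.80
UA	C	C	-0.80
UA	C	G	-0.80
UA	C	U	-0.80
UA	G	A	-1.10
UA	G	C	-0.80
UA	G	G	-1.10
UA	G	U	-0.80
UA	U	A	-0.80
UA	U	C	-0.80
UA	U	G	-0.80
UA	U	U	-1.00
GC	A	A	-1.20
GC	A	C	-1.20
GC	A	G	-1.50
GC	A	U	-1.20
GC	C	A	-1.20
GC	C	C	-1.20
GC	C	G	-1.20
GC	C	U	-1.20
GC	G	A	-1.50
GC	G	C	-1.20
GC	G	G	-1.50
GC	G	U	-1.20
GC	U	A	-1.20
GC	U	C	-1.20
GC	U	G	-1.20
GC	U	U	-1.40
CG	A	A	-1.10
CG	A	C	-1.10
CG	A	G	-1.40
CG	A	U	-1.10
CG	C	A	-1.10
CG	C	C	-1.10
CG	C	G	-1.10
CG	C	U	-1.10
CG	G	A	-1.40
CG	G	C	-1.10
CG	G	G	-1.40
CG	G	U	-1.10
CG	U	A	-1.10
CG	U	C	-1.10
CG	U	G	-1.10
CG	U	U	-1.30
GU	A	A	-0.70
GU	A	C	-0.70
GU	A	G	-1.00
GU	A	U	-0.70
GU	C	A	-0.70
GU	C	C	-0.70
GU	C	G	-0.70
GU	C	U	-0.70
GU	G	A	-1.00
GU	G	C	-0.70
GU	G	G	-1.00
GU	G	U	-0.70
GU	U	A	-0.70
GU	U	C	-0.70
GU	U	G	-0.70
GU	U	U	-0.90
UG	A	A	-0.70
UG	A	C	-0.70
UG	A	G	-1.00
UG	A	U	-0.70
UG	C	A	-0.70
UG	C	C	-0.70
UG	C	G	-0.70
UG	C	U	-0.70
UG	G	A	-1.00
UG	G	C	-0.70
UG	G	G	-1.00
UG	G	U	-0.70
UG	U	A	-0.70
UG	U	C	-0.70
UG	U	G	-0.70
UG	U	U	-0.90
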