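# Dangling-end increments dG_d(closing, base, side) kcal/mol.
closing	base	side	dg
AU	A	5	-0.30
AU	C	5	-0.10
AU	G	5	-0.20
AU	U	5	-0.20
UA	A	5	-0.30
UA	C	5	-0.20
UA	G	5	-0.10
UA	U	5	-0.20
GC	A	5	-0.20
GC	C	5	-0.30
GC	G	5	-0.00
GC	U	5	-0.00
CG	A	5	-0.30
CG	C	5	-0.30
CG	G	5	-0.40
CG	U	5	-0.20
GU	A	5	-0.30
GU	C	5	-0.10
GU	G	5	-0.20
GU	U	5	-0.20
UG	A	5	-0.30
UG	C	5	-0.20
UG	G	5	-0.10
UG	U	5	-0.20
AU	A	3	-0.70
AU	C	3	-0.10
AU	G	3	-0.70
AU	U	3	-0.10
UA	A	3	-0.80
UA	C	3	-0.50
UA	G	3	-0.80
UA	U	3	-0.60
GC	A	3	-1.10
GC	C	3	-0.40
GC	G	3	-1.30
GC	U	3	-0.60
CG	A	3	-1.70
CG	C	3	-0.80
CG	G	3	-1.70
CG	U	3	-1.20
GU	A	3	-0.70
GU	C	3	-0.10
GU	G	3	-0.70
GU	U	3	-0.10
UG	A	3	-0.80
UG	C	3	-0.50
UG	G	3	-0.80
UG	U	3	-0.60
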