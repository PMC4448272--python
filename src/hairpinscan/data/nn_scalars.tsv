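# Scalar NN constants. Energies kcal/mol; R in J/(mol K); T in K.
name	value
asym_penalty	0.6
ru_closure	0.7
ru_end	0.45
c_bulge	-0.9
sym_correction	0.43
gas_constant	8.3144621
temperature	310.15
long_loop_coeff	1.75
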