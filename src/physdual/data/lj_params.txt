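# Element-keyed 12-6 Lennard-Jones parameters (GAFF-like representative values).
# Columns: type  sigma[A]  epsilon[kcal/mol]
c   3.3997  0.1094
n   3.2500  0.1700
o   2.9599  0.2100
s   3.5636  0.2500
f   3.1181  0.0610
cl  3.4709  0.2656
br  3.5990  0.4200
i   3.8300  0.5000
p   3.7418  0.2000
h   2.6000  0.0157
# Coarse residue-level bead used when a protein context is supplied as one
# representative particle per residue (C-alpha convention).
ca  4.0000  0.1000
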