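# Ionizable-group pKa values (EMBOSS set).
# Side chains D, E, C, Y are acidic (contribute negative charge above
# their pKa); H, K, R are basic (positive below). Termini: Nterm basic,
# Cterm acidic.
D	3.9
E	4.1
C	8.5
Y	10.1
H	6.5
K	10.8
R	12.5
Nterm	8.6
Cterm	3.6
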