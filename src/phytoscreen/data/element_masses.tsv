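# Monoisotopic atomic masses (unified atomic mass units), CODATA/IUPAC 2021
# symbol	monoisotopic_mass
H	1.00782503207
C	12.0
N	14.0030740048
O	15.9949146196
S	31.97207100
P	30.97376163
F	18.99840322
Cl	34.96885268
Br	78.9183371
I	126.904473
Na	22.9897692809
K	38.96370668
Si	27.9769265325
Se	79.9165213
B	11.0093054
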