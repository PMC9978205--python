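# van der Waals radii (Å) for solvent-accessible surface area
# element	radius
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
H	1.20
SE	1.90
default	1.70
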