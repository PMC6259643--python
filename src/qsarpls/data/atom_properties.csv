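# Atomic property table for descriptor weighting.
# Sources: atomic masses — IUPAC standard atomic weights (2021, abridged);
# van der Waals volumes — (4/3)*pi*r^3 from Bondi (1964) van der Waals radii;
# Sanderson electronegativities — Sanderson (1983) scale;
# polarizabilities — CRC Handbook static dipole polarizabilities (A^3).
# Values are raw; carbon scaling (w_i / w_C) is applied at lookup time when enabled.
element,mass,volume,electronegativity,polarizability
H,1.008,7.236,2.592,0.667
C,12.011,20.577,2.746,1.760
N,14.007,15.597,3.194,1.100
O,15.999,14.711,3.654,0.802
F,18.998,13.304,4.000,0.557
Si,28.085,38.788,2.138,5.380
P,30.974,24.426,2.515,3.630
S,32.060,24.426,2.957,2.900
Cl,35.453,22.449,3.475,2.180
Br,79.904,26.518,3.219,3.050
I,126.904,32.512,2.778,5.350
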