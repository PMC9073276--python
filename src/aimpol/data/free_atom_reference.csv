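# Free-atom reference data for the Tkatchenko-Scheffler scaling law.
# alpha_free and c6_free are literature-style free-atom static polarizabilities
# and homo-atomic C6 coefficients in Hartree atomic units.  r3_free is the
# free-atom <r^3> radial moment (a.u.) used as the scaling denominator; only
# hydrogen's value is an exact closed form (7.5 a.u. for the 1s ground state),
# the rest are representative reference scales (synthetic) -- supply your own
# table for production work via the reference= argument.
element,alpha_free,c6_free,r3_free
H,4.50,6.50,7.5
He,1.38,1.46,2.37
Li,164.2,1387.0,93.0
B,21.0,99.5,22.8
C,12.0,46.6,14.7
N,7.40,24.2,11.2
O,5.40,15.6,9.6
F,3.80,9.52,8.4
Ne,2.67,6.38,7.1
Na,162.7,1556.0,96.2
Mg,71.0,627.0,60.6
Si,37.0,305.0,36.0
P,25.0,185.0,28.5
S,19.6,134.0,24.8
Cl,15.0,94.6,21.5
Ar,11.1,64.3,18.6
K,292.9,3897.0,147.0
Ca,160.0,2221.0,106.0
Br,20.0,162.0,27.5
Kr,16.8,130.0,24.3
I,35.0,385.0,40.2
Xe,27.3,286.0,35.1
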