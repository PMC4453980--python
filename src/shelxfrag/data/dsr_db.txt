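<water>
RESI H2O
REM idealized water, the only entry carrying explicit hydrogens
DFIX 0.9584 O1 H1 O1 H2
DANG 1.5151 H1 H2
FRAG 17 1 1 1 90 90 90
O1   -8   0.000000   0.000000   0.000000
H1   -1   0.757541   0.000000   0.587080
H2   -1  -0.757541   0.000000   0.587080
</water>

<OC(CF3)3>
RESI CCF3
REM perfluorinated tert-butoxide, O1 is the alkoxide oxygen
SADI 0.02 C1 C2 C1 C3 C1 C4
SADI 0.02 F1 C2 F2 C2 F3 C2 F4 C3 F5 C3 =
  F6 C3 F7 C4 F8 C4 F9 C4
SADI 0.04 C2 C3 C3 C4 C2 C4
SADI 0.04 O1 C2 O1 C3 O1 C4
SADI 0.04 F1 F2 F2 F3 F3 F1 F4 F5 F5 F6 F6 F4 F7 F8 F8 F9 F9 F7
SADI 0.1 F1 C1 F2 C1 F3 C1 F4 C1 F5 C1 F6 C1 F7 C1 F8 C1 F9 C1
FRAG 17 1 1 1 90 90 90
O1   -8   0.000000   0.000000   1.380000
C1   -6   0.000000   0.000000   0.000000
C2   -6   1.461356   0.000000  -0.516661
C3   -6  -0.730678   1.265571  -0.516661
C4   -6  -0.730678  -1.265571  -0.516661
F1   -9   1.517359  -0.626968  -1.688273
F2   -9   1.879335   1.253936  -0.664437
F3   -9   2.241311  -0.626968   0.359399
F4   -9  -0.215709   1.627555  -1.688273
F5   -9  -2.025608   1.000584  -0.664437
F6   -9  -0.577686   2.254517   0.359399
F7   -9  -1.301650  -1.000587  -1.688273
F8   -9   0.146273  -2.254520  -0.664437
F9   -9  -1.663626  -1.627549   0.359399
</OC(CF3)3>

<toluene>
RESI TOL
REM C1 carries the methyl carbon C7; no ring hydrogens in the entry
SADI 0.02 C1 C2 C2 C3 C3 C4 C4 C5 C5 C6 C6 C1
SADI 0.04 C1 C3 C2 C4 C3 C5 C4 C6 C5 C1 C6 C2
DFIX 1.510 C1 C7
DANG 2.512 C2 C7 C6 C7
FLAT C1 > C7
HFIX 43 C2 C3 C4 C5 C6
HFIX 137 C7
SIMU C1 > C7
RIGU C1 > C7
FRAG 17 1 1 1 90 90 90
C1   -6   1.390000   0.000000   0.000000
C2   -6   0.695000   1.203775   0.000000
C3   -6  -0.695000   1.203775   0.000000
C4   -6  -1.390000   0.000000   0.000000
C5   -6  -0.695000  -1.203775   0.000000
C6   -6   0.695000  -1.203775   0.000000
C7   -6   2.900000   0.000000   0.000000
</toluene>

<THF>
RESI THF
REM twisted (C2) conformer of tetrahydrofuran; invert to reach the enantiomer
SADI 0.02 O1 C2 O1 C5
SADI 0.02 C2 C3 C4 C5
DFIX 1.539 C3 C4
SADI 0.04 O1 C3 O1 C4
SADI 0.04 C2 C4 C3 C5
DANG 2.282 C2 C5
SIMU O1 > C5
RIGU O1 > C5
FRAG 17 1 1 1 90 90 90
O1   -8   1.180000   0.000000   0.000000
C2   -6   0.364640   1.122247  -0.205725
C3   -6  -0.954640   0.693587   0.332870
C4   -6  -0.954640  -0.693587  -0.332870
C5   -6   0.364640  -1.122247   0.205725
</THF>

<DCM>
RESI DCM
REM dichloromethane heavy atoms
DFIX 1.770 C1 CL1 C1 CL2
DANG 2.935 CL1 CL2
SIMU C1 > CL2
RIGU C1 > CL2
FRAG 17 1 1 1 90 90 90
C1   -6   0.000000   0.000000   0.000000
CL1  -17  1.467397   0.000000   0.989771
CL2  -17 -1.467397   0.000000   0.989771
</DCM>

<tert-butyl>
RESI TBU
REM tert-butyl group; C1 is the attachment carbon
SADI 0.02 C1 C2 C1 C3 C1 C4
SADI 0.04 C2 C3 C3 C4 C2 C4
HFIX 137 C2 C3 C4
SIMU C1 > C4
RIGU C1 > C4
FRAG 17 1 1 1 90 90 90
C1   -6   0.000000   0.000000   0.000000
C2   -6   1.451928   0.000000  -0.513328
C3   -6  -0.725964   1.257406  -0.513328
C4   -6  -0.725964  -1.257406  -0.513328
</tert-butyl>
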