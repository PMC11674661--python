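electrode,row,col
Af7,0,0
Fp1,0,1
Af3,0,2
Fpz,0,3
Fp2,0,4
Af4,0,5
Af8,0,6
F7,1,0
F5,1,1
F3,1,2
Afz,1,3
F4,1,4
F6,1,5
F8,1,6
Ft7,2,0
Fc5,2,1
F1,2,2
Fz,2,3
F2,2,4
Fc6,2,5
Ft8,2,6
Fc3,3,0
Fc1,3,1
Fcz,3,2
Cz,3,3
Fc2,3,4
C2,3,5
Fc4,3,6
T7,4,0
C5,4,1
C3,4,2
C1,4,3
C4,4,4
C6,4,5
T8,4,6
T9,5,0
Cp3,5,1
Cp1,5,2
Cpz,5,3
Cp2,5,4
Cp4,5,5
T10,5,6
Tp7,6,0
Cp5,6,1
P1,6,2
Pz,6,3
P2,6,4
Cp6,6,5
Tp8,6,6
P7,7,0
P5,7,1
P3,7,2
Poz,7,3
P4,7,4
P6,7,5
P8,7,6
Po7,8,0
Po3,8,1
O1,8,2
Oz,8,3
O2,8,4
Po4,8,5
Po8,8,6
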