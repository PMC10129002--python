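# Metabolic insulin signaling cascade, written as a mass-action CRN
# (after the Sedaghat et al. 2002 model; insulin input folded into the
# binding rate constants, modifier-dependent steps written as catalytic
# bimolecular reactions).
# Species: X2  free surface receptor;       X3  once-bound surface receptor;
#          X4/X5 twice/once-bound phosphorylated surface receptor;
#          X6  free intracellular receptor; X7/X8 phosphorylated internalized;
#          X9/X10 IRS-1 (unphos/phos);      X11 PI3K;  X12 IRS-1:PI3K complex;
#          X13 PI(3,4,5)P3;  X14 PI(4,5)P2; X15 PI(3,4)P2;
#          X16/X17 Akt (inactive/active);   X18/X19 PKC (inactive/active);
#          X20/X21 GLUT4 (intracellular/cell surface).
# Five conserved pools: x9+x10+x12, x11+x12, x13+x14+x15, x16+x17, x18+x19.
R1:  X2 -> X3          [k1]
R2:  X3 -> X2          [k2]
R3:  X3 -> X5          [k3]
R4:  X5 -> X3          [k4]
R5:  X5 -> X4          [k5]
R6:  X4 -> X5          [k6]
R7:  X4 -> X7          [k7]
R8:  X7 -> X4          [k8]
R9:  X5 -> X8          [k9]
R10: X8 -> X5          [k10]
R11: X2 -> X6          [k11]
R12: X6 -> X2          [k12]
R13: 0 -> X6           [k13]
R14: X6 -> 0           [k14]
R15: X7 -> X6          [k15]
R16: X8 -> X6          [k16]
R17: X9 + X4 -> X10 + X4   [k17]
R18: X9 + X5 -> X10 + X5   [k18]
R19: X10 -> X9         [k19]
R20: X10 + X11 -> X12  [k20]
R21: X12 -> X10 + X11  [k21]
R22: X14 + X12 -> X13 + X12 [k22]
R23: X13 -> X14        [k23]
R24: X13 -> X15        [k24]
R25: X15 -> X13        [k25]
R26: X16 + X13 -> X17 + X13 [k26]
R27: X17 -> X16        [k27]
R28: X18 + X13 -> X19 + X13 [k28]
R29: X19 -> X18        [k29]
R30: X20 -> X21        [k30]
R31: X20 + X17 -> X21 + X17 [k31]
R32: X20 + X19 -> X21 + X19 [k32]
R33: X21 -> X20        [k33]
R34: 0 -> X20          [k34]
R35: X20 -> 0          [k35]
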