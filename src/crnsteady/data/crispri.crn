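# CRISPRi toggle switch (mutual repression by dCas9:sgRNA complexes;
# mass-action model of the synthetic circuit of Santos-Moreno et al. 2020).
# Species: S, T  sgRNA1/sgRNA2;  C  dCas9;  CS, CT  dCas9:sgRNA complexes;
#          G, H  target genes;  R = CT:G and P = CS:H  bound (repressed) genes.
# Gene totals are conserved: h + p and g + r.
R1:  G -> G + S  [k1]
R2:  H -> H + T  [k2]
R3:  S + C -> CS [k3]
R4:  CS -> S + C [k4]
R5:  T + C -> CT [k5]
R6:  CT -> T + C [k6]
R7:  CS + H -> P [k7]
R8:  P -> CS + H [k8]
R9:  CT + G -> R [k9]
R10: R -> CT + G [k10]
R11: C -> 0      [k11]
R12: 0 -> C      [k12]
R13: S -> 0      [k13]
R14: T -> 0      [k14]
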