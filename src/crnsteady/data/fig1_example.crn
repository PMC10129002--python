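# Six-reaction illustration network over species A, B, C, D.
# Deficiency 1, not weakly reversible (B + C -> B lies on no cycle).
# Finest independent decomposition: {R1..R4} and {R5, R6}.
# The subnetwork {R1..R4} admits a weakly reversible, deficiency-zero
# translation by shifting B + C -> B to A + C -> A (one phantom edge).
R1: A + C -> 0 [k1]
R2: 0 -> A [k2]
R3: A -> A + C [k3]
R4: B + C -> B [k4]
R5: B -> D [k5]
R6: D -> B [k6]
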