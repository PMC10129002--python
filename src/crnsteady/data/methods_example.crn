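# Four-reaction birth/death example: two species produced from nothing,
# A removed on encounter with B, B degraded.  Rank s = 2; the partition
# {R1,R3} | {R2,R4} is independent (1 + 1 = 2).
R1: 0 -> A [k1]
R2: 0 -> B [k2]
R3: A + B -> B [k3]
R4: B -> 0 [k4]
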