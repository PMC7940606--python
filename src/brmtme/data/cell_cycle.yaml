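# Default G1/S and G2/M phase gene lists (short working versions of the
# commonly used cell-cycle phase signatures; supply your own for real data).
g1s: [MCM5, PCNA, TYMS, FEN1, MCM2, MCM4, RRM1, UNG, GINS2, MCM6]
g2m: [HMGB2, CDK1, NUSAP1, UBE2C, BIRC5, TPX2, TOP2A, MKI67, CENPF, AURKB]
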