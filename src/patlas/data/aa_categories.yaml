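# Side-chain polarity categories (standard biochemistry; editable).
# Every one of the 20 canonical amino acids appears in exactly one category.
nonpolar: [G, A, V, L, I, P, F, M, W]
polar_uncharged: [S, T, C, Y, N, Q]
polar_positive: [K, R, H]
polar_negative: [D, E]
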