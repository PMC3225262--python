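"""Consensus sequence, frequency matrix and Van der Waals volumes.

Analyses the five experimentally validated consensus nonamers (one per
published scoring function, all high-affinity HLA-A*02:01 binders) the way
a sweep's best-of-generation-50 peptides would be analysed.
"""

from pepga import (
    consensus_sequence,
    position_frequency_matrix,
    vdw_volume,
)

peptides = ["YMMEWMWYV", "YLAEGLASL", "MLWTMVFTV", "FLWEVTPTV", "WWWFFWYVW"]

print("peptide    volume (A^3)")
for p in peptides:
    print(f"{p}  {vdw_volume(p):g}")
print(f"poly-W     {vdw_volume('W' * 9):g}  (theoretical nonamer maximum)")

consensus = consensus_sequence(peptides)
print(f"\nconsensus of the five: {consensus} ({vdw_volume(consensus):g} A^3)")

pfm = position_frequency_matrix(peptides)
print("\nper-position information content (bits, of log2(20) = 4.32 max):")
print("  ".join(f"{ic:.2f}" for ic in pfm.information_content()))

# Bulky aromatic residues (W, Y, F) dominate several positions, which is why
# the volumes sit close to the 1467 A^3 poly-W ceiling: predictors reward
# peptides that fill the MHC binding groove.
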