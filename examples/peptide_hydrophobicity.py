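"""Hydrophobicity and theoretical masses of ABri/ADan/Abeta proteoforms.

C-terminal trimming of ADan *increases* its hydrophobic residue fraction
while trimming ABri decreases it — one candidate explanation for why ADan
co-aggregates with Abeta in Danish dementia while ABri in British dementia
does not.  This script prints the fraction and the theoretical
monoisotopic [M+H]+ for a few key spans.
"""

from vesselmap import proteoforms as pf

spans = [
    (pf.Precursor.BRI2_BRITISH, 1, 34),
    (pf.Precursor.BRI2_BRITISH, 1, 29),
    (pf.Precursor.BRI2_DANISH, 1, 34),
    (pf.Precursor.BRI2_DANISH, 1, 29),
    (pf.Precursor.BRI2_DANISH, 1, 28),
    (pf.Precursor.APP, 1, 40),
    (pf.Precursor.APP, 1, 42),
]

print(f"{'species':<12} {'hydrophobic %':>13} {'[M+H]+ (Da)':>12}")
for prec, start, end in spans:
    sp = pf.ProteoformSpecies(prec, start, end)
    frac = pf.hydrophobic_fraction(sp.sequence)
    print(f"{sp.display_name:<12} {frac:>13.1f} {pf.mz(sp):>12.3f}")

# pyroglutamate formation removes a water and a polar terminus
pe = pf.ProteoformSpecies(pf.Precursor.BRI2_DANISH, 1, 34, n_term_pyroglu=True)
print(f"\n{pe.display_name}: pE shifts [M+H]+ by "
      f"{pf.mz(pe) - pf.mz(pf.ProteoformSpecies(pf.Precursor.BRI2_DANISH, 1, 34)):+.3f} Da")
print("Higher percentages mean a more aggregation-prone, hydrophobic peptide.")
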