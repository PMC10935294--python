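# Protease cleavage specificity rules, BIOPEP "Enzyme action" style.
#
# Each rule describes where an enzyme cuts a peptide bond between residue i
# (the P1 position) and residue i+1 (the P1' position); P2 is residue i-1.
#   p1_classes:          residues allowed at P1 (empty list = unrestricted)
#   p1prime_exclusions:  residues at P1' that BLOCK cleavage
#   p2_classes:          residues required at P2 (empty list = no constraint;
#                        a non-empty P2 class can never match at the first bond)
#
# These defaults follow the common Keil/BIOPEP conventions.  Exact specificity
# differs between BIOPEP releases — edit this file to match the release you
# need; rules are data, never code.
trypsin:
  p1_classes: [K, R]
  p1prime_exclusions: [P]
  p2_classes: []
papain:
  p1_classes: []
  p1prime_exclusions: [P]
  p2_classes: [A, V, L, I, F, W, Y]
pepsin_ph2:
  p1_classes: [F, L, W, Y]
  p1prime_exclusions: [P]
  p2_classes: []
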