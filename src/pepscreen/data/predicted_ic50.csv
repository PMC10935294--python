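# QSAR-predicted IC50 values (µM) for the 21 peptides released in silico from
# Larimichthys crocea myosin heavy chain and confirmed in the <3 kDa hydrolysate.
# Provenance note: the octapeptide LYDQHLGK is printed here as in the source
# prediction table; the same candidate appears elsewhere in the study as the
# heptapeptide spelling LYDHLGK (the synthesised form).  Both spellings refer to
# the same screening hit; this fixture keeps the prediction-table spelling as
# the data row and records the variant in the alt_spelling column.
peptide,predicted_ic50_uM,alt_spelling
TVK,205.63,
TIR,219.84,
YNL,43.40,
EAEFQK,416.43,
FYEPFM,9.53,
SFTNVK,52.93,
LEGDLK,233.12,
NWPWMK,8.19,
IPYADFK,0.64,
SIHEIEK,23.51,
LQDLVDK,112.97,
VDYNIIG,15.26,
TEELEEAK,12.74,
LYDQHLGK,3.25,LYDHLGK
AALEQTER,37.25,
INEMLDTK,1.82,
DEEMEQIK,30.98,
NLEVAVK,11.29,
VLDTEEER,16.77,
IHFGTTGK,7.87,
ELEEISER,56.22,
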