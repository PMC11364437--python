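# Residue-name -> molecular-category dictionary (uppercase names).
# Unlisted residues fall into "other". One-letter codes shared between
# ions and ribonucleotides (K, NA...) resolve by exact-name priority to
# water_ions; flagged here rather than silently decided.
protein:
  - ALA
  - ARG
  - ASN
  - ASP
  - CYS
  - GLN
  - GLU
  - GLY
  - HIS
  - ILE
  - LEU
  - LYS
  - MET
  - PHE
  - PRO
  - SER
  - THR
  - TRP
  - TYR
  - VAL
  # protonation / tautomer variants
  - HID
  - HIE
  - HIP
  - HSD
  - HSE
  - HSP
  - CYX
  - CYM
  - LYN
  - ASH
  - GLH
  # termini and caps
  - ACE
  - NME
  - NH2
  - NMA
lipid:
  - POPC
  - POPE
  - POPG
  - POPS
  - DPPC
  - DOPC
  - DOPE
  - DMPC
  - DSPC
  - DLPC
  - DOPS
  - CHOL
  - CHL1
  - CARD
  # Martini codes
  - DPPE
  - DIPC
  - DPSM
  - POP2
nucleic:
  - DA
  - DT
  - DG
  - DC
  - DU
  - RA
  - RU
  - RG
  - RC
  - A
  - U
  - G
  - C
  - DA5
  - DA3
  - DT5
  - DT3
  - DG5
  - DG3
  - DC5
  - DC3
glucid:
  - GLC
  - GAL
  - MAN
  - NAG
  - NDG
  - BMA
  - BGLC
  - BGAL
  - FRU
  - SUC
  - XYL
  - FUC
  - SIA
water_ions:
  - SOL
  - WAT
  - HOH
  - TIP3
  - TIP4
  - TIP5
  - SPC
  - SPCE
  - W
  - WF
  - NA
  - CL
  - K
  - MG
  - CA
  - ZN
  - ION
  - NA+
  - CL-
  - K+
  - CA2+
  - SOD
  - POT
  - CLA
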