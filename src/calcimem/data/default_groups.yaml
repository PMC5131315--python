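# Group-map template: (residue name -> atom name -> group tag).
# Covers Berger-style united-atom POPC/POPS with SPC water, plus the atom
# names emitted by the synthetic bilayer generator.  Edit to match your
# topology's naming; unmapped atoms fall back to OTHER.
POPC:
  P: PHOS_P        # phosphate phosphorus
  P8: PHOS_P       # Berger numbering
  N: CHOL_N        # choline nitrogen
  N4: CHOL_N
  OS1: CARBONYL_O_SN1
  OS2: CARBONYL_O_SN2
  O16: CARBONYL_O_SN1   # sn-1 ester carbonyl O, Berger numbering
  O35: CARBONYL_O_SN2   # sn-2 ester carbonyl O
POPS:
  P: PHOS_P
  P8: PHOS_P
  N: CHOL_N        # serine amine nitrogen (P-N vector defined analogously)
  N4: CHOL_N
  OS1: CARBONYL_O_SN1
  OS2: CARBONYL_O_SN2
  O16: CARBONYL_O_SN1
  O35: CARBONYL_O_SN2
  OC1: COO_PS      # carboxylate oxygens (counted once per group)
  OC2: COO_PS
  O13A: COO_PS
  O13B: COO_PS
SOL:
  OW: WATER_O
CA:
  CA: CA
CL:
  CL: CL
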