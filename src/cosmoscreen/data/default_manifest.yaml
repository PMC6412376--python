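# Default screening manifest: 16 cations x 22 anions = 352 ionic liquids,
# the cation/anion pool drawn from the lipid-extraction IL literature.
# Charges: cations +1; anions -1 except sulfate (-2).
solute: EPA
temperature: 298.15
cations:
  - "[EMIM]"      # 1-ethyl-3-methyl imidazolium
  - "[BMIM]"      # 1-butyl-3-methyl imidazolium
  - "[HMIM]"      # 1-hexyl-3-methyl imidazolium
  - "[OMIM]"      # 1-octyl-3-methyl imidazolium
  - "[EMPyr]"     # 1-ethyl-3-methyl pyridinium
  - "[BMPyr]"     # 1-butyl-3-methyl pyridinium
  - "[HMPyr]"     # 1-hexyl-3-methyl pyridinium
  - "[OMPyr]"     # 1-octyl-3-methyl pyridinium
  - "[EMPyrro]"   # 1-ethyl-1-methyl pyrrolidinium
  - "[BMPyrro]"   # 1-butyl-1-methyl pyrrolidinium
  - "[HMPyrro]"   # 1-hexyl-1-methyl pyrrolidinium
  - "[MOPyrro]"   # 1-methyl-1-octyl pyrrolidinium
  - "[MPPIP]"     # 1-methyl-1-propyl piperidinium
  - "[BMPIP]"     # 1-butyl-1-methyl piperidinium
  - "[HMPIP]"     # 1-hexyl-1-methyl piperidinium
  - "[TMAm]"      # tetra-methyl ammonium
anions:
  - "[Cl]"          # chloride
  - "[Br]"          # bromide
  - "[BF4]"         # tetrafluoroborate
  - "[PF6]"         # hexafluorophosphate
  - "[NO3]"         # nitrate
  - "[DCN]"         # dicyanamide
  - "[DEP]"         # diethylphosphate
  - "[AlCl4]"       # tetrachloroaluminate
  - "[MeSO4]"       # methyl sulfate
  - "[SCN]"         # thiocyanate
  - "[MeSO3]"       # methanesulfonate
  - "[EtSO4]"       # ethyl sulfate
  - "[Benzoate]"    # benzoate
  - id: "[SO4]"     # sulfate, divalent
    charge: -2
  - "[HSO4]"        # hydrogensulfate
  - "[DMP]"         # dimethylphosphate
  - "[Propanoate]"  # propanoate
  - "[TOS]"         # toluene-4-sulfonate
  - "[OTf]"         # trifluoromethanesulfonate
  - "[NHTf2]"       # bis(trifluoromethyl)imide
  - "[TFA]"         # trifluoroacetate
  - "[Tf2N]"        # bis(trifluoromethylsulfonyl)imide
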