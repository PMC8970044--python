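name,kind,value_da,source,note
proton,physical,1.007276,computed,mass of H+
water,physical,18.010565,computed,monoisotopic H2O
carbamidomethyl,modification,57.021464,computed,fixed Cys alkylation delta
oxidation,modification,15.994915,computed,variable Met oxidation delta
deamidation,modification,0.984016,computed,variable Asn/Gln deamidation delta
HexNAc,monosaccharide_residue,203.079373,computed,N-acetylhexosamine residue
Hex,monosaccharide_residue,162.052824,computed,hexose residue (Man/Gal/Glc isomers)
Fuc,monosaccharide_residue,146.057909,computed,deoxyhexose (fucose) residue
NeuAc,monosaccharide_residue,291.095417,computed,N-acetylneuraminic acid residue
HexNAc_frag_138,oxonium_mz,138.05,published_literal,HexNAc secondary fragment; no residue-sum form
HexNAc_frag_168,oxonium_mz,168.05,published_literal,HexNAc secondary fragment; common literature value 168.066 - published table value kept
HexNAc_oxonium,oxonium_mz,204.0866,computed,HexNAc + proton
NeuAc_minus_H2O_oxonium,oxonium_mz,274.0921,computed,NeuAc - H2O + proton
NeuAc_oxonium,oxonium_mz,292.1027,computed,NeuAc + proton
HexNAcHex_oxonium,oxonium_mz,366.1395,computed,HexNAc + Hex + proton
HexNAcHexFuc_oxonium,oxonium_mz,512.1974,computed,outer-arm fucosylation diagnostic (Hex isomer Gal/Glc unresolved)
HexNAcHexNeuAc_oxonium,oxonium_mz,657.2349,computed,sialylation diagnostic
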