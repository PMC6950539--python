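metabolite,grade_g1,perineural_invasion,angioinvasion,parietal_infiltration,tumor_secretion,metastases_at_diagnosis,multifocality,tumor_vs_normal_si,mets_vs_primary,mets_vs_normal_liver
taurine,0,1,1,1,0,0,1,1.5,0,1.5
aspartate,1,1,0,-1,-1,1,1,-1.5,0,1.5
serine,1,-1,-1,-1,-1,-1,-1,0,0,0
acetate,1,1,-1,-1,-1,-1,-1,0,0,1.5
NAA,1,-1,-1,1,1,-1,-1,0,0,0
isoleucine,1,-1,-1,1,-1,1,-1,0,0,0
glucose,1,-1,0,-1,-1,-1,0,0,1.5,-1.5
glycine,-1,0,-1,-1,0,0,0,0,0,0
valine,1,-1,-1,0,-1,1,-1,0,-1.5,-1.5
lactate,0,1,1,1,1,1,1,0,0,1.5
alanine,0,0,-1,1,-1,1,-1,-1.5,1.5,-1.5
myo-inositol,0,0,0,1,0,0,1,1.5,-1.5,0
ascorbate,1,0,0,-1,1,1,0,0,0,0
glutathione,0,0,0,0,0,0,0,1.5,0,0
glutamate,0,0,-1,1,0,0,0,0,0,0
scyllo-inositol,0,-1,0,1,-1,0,1,0,0,0
succinate,1,-1,0,0,0,0,1,1.5,-1.5,1.5
fumarate,0,1,-1,-1,1,-1,-1,0,0,0
glutamine,1,0,-1,1,1,-1,0,0,0,0
arginine,1,0,-1,1,1,1,1,0,0,0
creatine,1,0,-1,-1,-1,1,1,-1.5,0,0
ethanolamine,1,-1,-1,0,0,1,0,-1.5,1.5,-1.5
choline,0,1,1,0,1,1,1,0,0,1.5
glycerophosphocholine,0,1,1,0,0,1,1,1.5,1.5,0
phosphorylcholine,0,0,0,-1,1,0,1,0,0,1.5
tyrosine,1,-1,-1,1,1,-1,-1,0,0,0
tryptophan,1,1,1,1,0,1,0,0,0,0
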