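metabolite,center_ppm,rel_area,linewidth_ppm,protons_per_molecule
taurine,3.423,0.5,0.0016,2
taurine,3.437,0.5,0.0016,2
aspartate,2.732,0.5,0.0016,2
aspartate,2.748,0.5,0.0016,2
serine,3.833,0.5,0.0016,1
serine,3.847,0.5,0.0016,1
acetate,1.920,1.0,0.0016,3
NAA,2.020,1.0,0.0016,3
isoleucine,0.933,0.5,0.0016,3
isoleucine,0.947,0.5,0.0016,3
glucose,5.226,0.5,0.0016,1
glucose,5.234,0.5,0.0016,1
glycine,3.630,1.0,0.0016,2
valine,1.033,0.5,0.0016,3
valine,1.047,0.5,0.0016,3
lactate,1.323,0.5,0.0016,3
lactate,1.337,0.5,0.0016,3
alanine,1.473,0.5,0.0016,3
alanine,1.487,0.5,0.0016,3
myo-inositol,4.060,1.0,0.0016,1
ascorbate,4.520,1.0,0.0016,1
glutathione,2.943,0.5,0.0016,2
glutathione,2.957,0.5,0.0016,2
glutamate,2.112,0.5,0.0016,2
glutamate,2.128,0.5,0.0016,2
scyllo-inositol,3.530,1.0,0.0016,12
succinate,2.410,1.0,0.0016,4
fumarate,6.520,1.0,0.0016,2
glutamine,2.512,0.5,0.0016,2
glutamine,2.528,0.5,0.0016,2
arginine,1.672,0.5,0.0016,2
arginine,1.688,0.5,0.0016,2
creatine,3.030,1.0,0.0016,3
ethanolamine,3.114,0.5,0.0016,2
ethanolamine,3.126,0.5,0.0016,2
choline,3.230,1.0,0.0016,9
glycerophosphocholine,3.714,0.5,0.0016,2
glycerophosphocholine,3.726,0.5,0.0016,2
phosphorylcholine,3.330,1.0,0.0016,9
tyrosine,6.891,0.5,0.0016,2
tyrosine,6.909,0.5,0.0016,2
tryptophan,7.536,0.5,0.0016,1
tryptophan,7.544,0.5,0.0016,1
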