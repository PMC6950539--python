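name,window_lo_ppm,window_hi_ppm,protons_in_window,baseline_nmol_per_mg
taurine,3.400,3.460,2,9.0
aspartate,2.710,2.770,2,1.5
serine,3.810,3.870,1,1.2
acetate,1.890,1.950,3,1.0
NAA,1.990,2.050,3,0.4
isoleucine,0.910,0.970,3,0.5
glucose,5.200,5.260,1,4.0
glycine,3.600,3.660,2,2.5
valine,1.010,1.070,3,0.6
lactate,1.300,1.360,3,12.0
alanine,1.450,1.510,3,2.8
myo-inositol,4.030,4.090,1,5.5
ascorbate,4.490,4.550,1,1.0
glutathione,2.920,2.980,2,1.8
glutamate,2.090,2.150,2,4.5
scyllo-inositol,3.500,3.560,12,0.5
succinate,2.380,2.440,4,0.9
fumarate,6.490,6.550,2,0.15
glutamine,2.490,2.550,2,3.0
arginine,1.650,1.710,2,0.8
creatine,3.000,3.060,3,4.0
ethanolamine,3.090,3.150,2,1.1
choline,3.200,3.260,9,1.6
glycerophosphocholine,3.690,3.750,2,1.9
phosphorylcholine,3.300,3.360,9,1.3
tyrosine,6.870,6.930,2,0.5
tryptophan,7.510,7.570,1,0.2
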