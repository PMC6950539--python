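glucose	lactate
glucose	serine
glucose	myo-inositol
glucose	ascorbate
serine	glycine
serine	ethanolamine
glycine	creatine
glycine	glutathione
lactate	alanine
lactate	acetate
acetate	succinate
succinate	fumarate
fumarate	aspartate
fumarate	tyrosine
aspartate	NAA
aspartate	glutamate
glutamate	glutamine
glutamate	glutathione
glutamate	succinate
glutamate	arginine
arginine	creatine
taurine	glutathione
valine	succinate
isoleucine	valine
tyrosine	tryptophan
ethanolamine	choline
choline	phosphorylcholine
phosphorylcholine	glycerophosphocholine
myo-inositol	scyllo-inositol
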