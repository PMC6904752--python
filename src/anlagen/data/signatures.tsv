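identity	genes
Mesenchymal stem cells	Pdgfra,Prrx1
Satellite cells/stromal progenitors	Pax7
Schwann cells/neural progenitors	Plp1,Cnp,Dhh
Myofibroblasts	Acta2,Mylk
Endothelial/vascular progenitor cells	Cdh5,Pecam1,Cd34
Lymphocytes	Ms4a1
Myeloid cells	Ccr2,Mrc1,Fcgr1,Ccr1,S100a9,Cd209a
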