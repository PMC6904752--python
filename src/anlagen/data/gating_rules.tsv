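subtype	positive	negative	priority
chondrocyte	Sox9,Acan,Col1a1,Col3a1		1
preosteoblast	Runx2,Col1a1		2
tenocyte	Scx,Col1a1		3
MSC	Pdgfra	Sox9,Runx2	4
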