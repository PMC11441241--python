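class_code	category	n_chains
TG	glycerolipid	3
DG	glycerolipid	2
MGDG	glycerolipid	2
DGDG	glycerolipid	2
PA	glycerophospholipid	2
PC	glycerophospholipid	2
PE	glycerophospholipid	2
PG	glycerophospholipid	2
PI	glycerophospholipid	2
LPC	glycerophospholipid	1
LPE	glycerophospholipid	1
Cer	sphingolipid	2
HexCer	sphingolipid	2
SM	sphingolipid	2
SE	sterol lipid	1
AHexSE	sterol lipid	1
CoQ	prenol lipid	1
PR	prenol lipid	1
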