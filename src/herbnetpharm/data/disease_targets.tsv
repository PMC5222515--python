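target_id	protein_name	uniprot_id
CHRM4	Muscarinic acetylcholine receptor M4	P08173
CHRM5	Muscarinic acetylcholine receptor M5	P08912
ADRA1A	Alpha-1A adrenergic receptor	P35348
ADRA1B	Alpha-1B adrenergic receptor	P35368
KCNMA1	Calcium-activated potassium channel subunit alpha-1	Q12791
OPRM1	Mu-type opioid receptor	P35372
PGR	Progesterone receptor	P06401
CHRM3	Muscarinic acetylcholine receptor M3	P20309
CHRM2	Muscarinic acetylcholine receptor M2	P08172
CHRM1	Muscarinic acetylcholine receptor M1	P11229
RXRA	Retinoic acid receptor RXR-alpha	P19793
TOP2A	DNA topoisomerase 2-alpha	P11388
CA2	Carbonic anhydrase 2	P00918
PTGS1	Prostaglandin G/H synthase 1	P23219
PTGS2	Prostaglandin G/H synthase 2	P35354
AR	Androgen receptor	P10275
NOS2	Nitric oxide synthase, inducible	P35228
NOS3	Nitric oxide synthase, endothelial	P29474
ESR1	Estrogen receptor	P03372
ESR2	Estrogen receptor beta	Q92731
CHEK1	Serine/threonine-protein kinase Chk1	O14757
PIM1	Serine/threonine-protein kinase pim-1	P11309
ADRA1D	Alpha-1D adrenergic receptor	P25100
ADRA2A	Alpha-2A adrenergic receptor	P08913
ADRA2B	Alpha-2B adrenergic receptor	P18089
ADRA2C	Alpha-2C adrenergic receptor	P18825
OPRD1	Delta-type opioid receptor	P41143
F10	Coagulation factor X	P00742
NR3C1	Glucocorticoid receptor	P04150
KDR	Vascular endothelial growth factor receptor 2	P35968
SLC6A3	Sodium-dependent dopamine transporter	Q01959
SLC6A2	Sodium-dependent noradrenaline transporter	P23975
SLC6A4	Sodium-dependent serotonin transporter	P31645
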