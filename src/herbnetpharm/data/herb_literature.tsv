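herb_id	name	n_total_articles	k_disease_articles
folium_artemisiae_argyi	Folium Artemisiae Argyi	52351	1114
dysosmae_verspiellis_rhixoma_et_radix	Dysosmae Verspiellis Rhixoma Et Radix	4339	499
atractylodes_macrocephala_koidz	Atractylodes Macrocephala Koidz	365271	9673
mylabris	Mylabris	14229	2419
radix_salviae	Radix Salviae	481101	13666
curcumae_rhizoma	Curcumae Rhizoma	73256	5610
stephaniae_tetrandrae_radix	Stephaniae Tetrandrae Radix	61204	3297
curcumae_longae_rhizoma	Curcumae longae Rhizoma	81457	8266
cortex_moutan	Cortex Moutan	62681	2185
caulis_akebiae	Caulis Akebiae	61689	1042
eriobotryae_folium	Eriobotryae Folium	18905	573
pseudobulbus_cremastrae_seu_pleiones	Pseudobulbus Cremastrae Seu Pleiones	16264	2294
crataegi_folium	Crataegi Folium	7699	377
cornus_officinalis_sieb_et_zucc	Cornus Officinalis Sieb. Et Zucc	68476	2209
asparagi_radix	Asparagi Radix	95185	11382
semiaquilegiae_radix	Semiaquilegiae Radix	3301	269
artemisiae_scopariae_herba	Artemisiae Scopariae Herba	89803	2121
gleditsiae_spina	Gleditsiae Spina	20102	1125
hedyotis_diffusa	Hedyotis Diffusa	62308	4719
ampelopsis_japonica_thunb_makino	Ampelopsis Japonica (Thunb.) Makino	4311	131
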