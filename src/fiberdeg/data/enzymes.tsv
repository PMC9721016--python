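ec	bonds
3.2.1.1	a1-4:Glc-Glc
3.2.1.2	a1-4:Glc-Glc
3.2.1.4	b1-4:Glc-Glc
3.2.1.6	b1-3:Glc-Glc;b1-4:Glc-Glc
3.2.1.7	b2-1:Fru-Fru
3.2.1.8	b1-4:Xyl-Xyl
3.2.1.11	a1-6:Glc-Glc
3.2.1.14	b1-4:GlcNAc-GlcNAc
3.2.1.15	a1-4:GalA-GalA
3.2.1.22	a1-6:Gal-Man
3.2.1.23	b1-4:Gal-Gal;b1-3:Gal-Gal;b1-6:Gal-Gal
3.2.1.25	b1-4:Man-Man
3.2.1.26	b2-1:Fru-Fru;a1-2:Glc-Fru
3.2.1.31	b1-4:GlcA-Glc;b1-2:GlcA-Man
3.2.1.37	b1-4:Xyl-Xyl
3.2.1.39	b1-3:Glc-Glc
3.2.1.40	a1-4:Rha-Glc;a1-2:Rha-GalA
3.2.1.41	a1-6:Glc-Glc;a1-4:Glc-Glc
3.2.1.52	b1-4:GlcNAc-GlcNAc
3.2.1.55	a1-2:Ara-Xyl;a1-3:Ara-Xyl;a1-3:Ara-Gal
3.2.1.59	a1-3:Glc-Glc
3.2.1.65	b2-6:Fru-Fru
3.2.1.67	a1-4:GalA-GalA
3.2.1.68	a1-6:Glc-Glc
3.2.1.70	a1-6:Glc-Glc
3.2.1.73	b1-3:Glc-Glc;b1-4:Glc-Glc
3.2.1.75	b1-6:Glc-Glc
3.2.1.78	b1-4:Man-Man;b1-4:Glc-Man;b1-4:Man-Glc
3.2.1.80	b2-1:Fru-Fru;b2-6:Fru-Fru
3.2.1.83	b1-4:Gal-Gal;a1-3:Gal-Gal
3.2.1.89	b1-4:Gal-Gal
3.2.1.91	b1-4:Glc-Glc
3.2.1.99	a1-5:Ara-Ara
3.2.1.151	b1-4:Glc-Glc;a1-6:Xyl-Glc
3.2.1.171	a1-2:Rha-GalA;a1-4:GalA-Rha
3.2.1.177	a1-6:Xyl-Glc
4.2.2.2	a1-4:GalA-GalA
4.2.2.3	b1-4:ManA-ManA;b1-4:ManA-GulA
4.2.2.10	a1-4:GalA-GalA
4.2.2.11	a1-4:GulA-GulA;b1-4:ManA-GulA
4.2.2.12	a1-3:Man-Glc;b1-4:Man-GlcA
4.2.2.23	a1-2:Rha-GalA;a1-4:GalA-Rha
4.2.2.25	b1-4:Glc-GlcA;b1-4:GlcA-Glc
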