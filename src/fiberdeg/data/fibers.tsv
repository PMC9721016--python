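name	abbreviation	bonds	solubility
inulin	Inu	b2-1:Fru-Fru;a1-2:Glc-Fru	soluble
levan	Lev	b2-6:Fru-Fru;a1-2:Glc-Fru	soluble
beta-glucan	BG	b1-3:Glc-Glc;b1-4:Glc-Glc	soluble
cellulose	Cel	b1-4:Glc-Glc	insoluble
xylan	Xyl	b1-4:Xyl-Xyl	insoluble
glucomannan	GluM	b1-4:Man-Man;b1-4:Glc-Man;b1-4:Man-Glc	soluble
galactomannan	GalM	b1-4:Man-Man;a1-6:Gal-Man	soluble
mannan	Man	b1-4:Man-Man	insoluble
arabinoxylan	AX	b1-4:Xyl-Xyl;a1-2:Ara-Xyl;a1-3:Ara-Xyl	soluble
galactan	Gal	b1-4:Gal-Gal	soluble
arabinan	Ara	a1-5:Ara-Ara;a1-3:Ara-Ara;a1-2:Ara-Ara	soluble
arabinogalactan	AG	b1-3:Gal-Gal;b1-6:Gal-Gal;a1-3:Ara-Gal	soluble
dextran	Dex	a1-6:Glc-Glc;a1-3:Glc-Glc	soluble
chitin	Chi	b1-4:GlcNAc-GlcNAc	insoluble
rhamnogalacturonan	RH	a1-2:Rha-GalA;a1-4:GalA-Rha;a1-5:Ara-Ara	soluble
pectin	Pec	a1-4:GalA-GalA	soluble
carrageenan	Car	b1-4:Gal-Gal;a1-3:Gal-Gal	soluble
galactoglucomannan	GalGluM	b1-4:Man-Man;b1-4:Glc-Man;b1-4:Man-Glc;a1-6:Gal-Man	soluble
alginate	Alg	b1-4:ManA-ManA;b1-4:ManA-GulA;a1-4:GulA-GulA	soluble
xanthan	Xan	b1-4:Glc-Glc;a1-3:Man-Glc;b1-2:GlcA-Man;b1-4:Man-GlcA	soluble
xyloglucan	XG	b1-4:Glc-Glc;a1-6:Xyl-Glc	insoluble
laminaran	Lam	b1-3:Glc-Glc;b1-6:Glc-Glc	soluble
gellan	Gel	b1-4:Glc-GlcA;b1-4:GlcA-Glc;b1-3:Glc-Rha;a1-4:Rha-Glc	soluble
resistant starch	RS	a1-4:Glc-Glc;a1-6:Glc-Glc	insoluble
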