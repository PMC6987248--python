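clade	fossil	period	locality	min_age	max_age	crown_stem
Ebenaceae	Austrodiospyros cryptostoma	Late Eocene	Anglesea formation (Victoria, Australia)	37.8	54.62	cr.
Apocynaceae	Apocynophyllum helveticum	Middle Eocene	Messel formation (Darmstadt, Germany)	47.8	64.62	cr.
Cornaceae	Hironoia fusiformis	Early Conacian	Ashizawa formation, Futuba group (North-eastern Honshu, Japan)	89.8	106.6	cr.
Dipelta	Dipelta europaea	Late Eocene-Early Oligocene	Bembridge Flora (UK)	33.9	50.72	st.
Oleaceae	Fraxinus wilcoxiana	Middle Eocene	Claiborne formation (Tennessee, USA)	47.8	64.62	st.
Diervilla	Diervilla echinata	Oligocene	Fraser River system (British Colombia, Canada)	27.8	44.62	st.
Solanaceae (Physalinae)	Physalis infinemundi	Early Eocene	Laguna del Hunco (Chubut, Patagonia, Argentina)	52.0	68.82	st.
Valeriana	Valeriana sp.	Late Miocene	Europe	11.6	28.42	st.
Emmenopterys	Emmenopterys	Middle Eocene	Middle Eocene Republic Flora (Washington, USA)	47.8	64.62	st.
Pelliciera	Pelliciera rhizophorae	Middle Eocene	Gatuncillo formation (Panama)	47.8	64.62	st.
Araliaceae	Acanthopanax gigantocarpus	Maastrichtian	Eisleben formation (Germany)	72.1	88.92	st.
Ilex	Ilex hercynica	Early Paleocene	Gonna formation (Sangerhausen, Germany)	66.0	82.82	st.
Actinidiaceae	Saurauia antiqua	Late Santonian	Klikov-Schichtenfolge (Germany)	85.8	102.6	st.
Nymphaeales	unnamed Nymphaeales	Late Aptian-Early Albian	Vale de Agua (Portugal)	112.0	128.8	cr.
Canellales	Walkeripollis gabonensis	Late Barremian-Early Aptian	Cocobeach (Gabon)	125.0	141.8	st.
Magnoliaceae	Archaeanthus linnenbergeri	Early Cenomanian	Dakota formation (Kansas, USA)	100.5	117.3	cr.
Magnoliales	Endressinia brasiliana	Aptian-Albian	Crato formation (Brasil)	112.0	128.8	cr.
Lauraceae	Potomacanthus lobatus	Early and Middle Albian	Puddledock locality (Virginia, USA)	119.0	135.8	cr.
Arecaceae	unnamed palms	Conacian-Santonian	Magothy formation (Maryland)	89.8	106.6	cr.
Musella-Ensete	Ensete oregonense	Middle Eocene	Clarno formation (Oregon, USA)	43.0	59.82	st.
Zingiberaceae	Zingiberopsis attenuata	Middle to late Paleocene	Paskapoo formation (Alberta, Canada)	61.6	78.42	cr.
Zingiberales	Spirematospermum chandlerae	Santonian-Campanian	Neuse River formation (North Carolina, USA)	83.6	100.4	cr.
Araceae	Mayoa portugallica	Barremanian-Aptian	Almargem formation (Torres Vedras, Portugal)	125.0	141.8	cr.
Restionaceae	unnamed Restionaceae	Maastrichtian	Morgan Creek (Saskatchewan, Canada)	72.1	88.92	st.
Poaceae	unnamed grasses	Maastrichtian	Senegal-Ivory Coast	72.1	88.92	cr.
Berberidaceae	Mahonia	Middle Eocene	Green River formation (Colorado-Utah, USA)	47.8	64.62	cr.
Platanaceae	Platanocarpus brookensis	Early and Middle Albian	Patapsco formation (Virginia, USA)	112.0	128.8	st.
Sabiales	Insitiocarpus moravicus	Early Cenomanian	Peruc-schichten (Czeck Republic)	98.0	114.8	cr.
Iteaceae	Divisestylus brevistamineus	Turonian	Raritan formation (New Jersey)	93.9	110.7	cr.
Altingiaceae	Microaltingia apocarpela	Turonian	Raritan formation (New Jersey)	93.9	110.7	cr.
Tilia	Tilia vescipites	Middle Paleocene	Wind River basin (Wyoming, USA)	61.6	78.42	cr.
Polygonaceae	Persicaria	Paleocene	Europe	66.0	82.82	cr.
Clausena	Clausena	Late Oligocene	Guang River Flora (Ethiopia)	27.36	44.18	cr.
Malpighiales	Paleoclusia chevalieri	Turonian	Raritan formation (New Jersey)	93.5	110.3	cr.
Fagales	Normapolles	Late Cenomanian	Europa and USA	94.7	111.5	cr.
Phytolaccaceae	Coahuilacarpon phytolaccoides	Late Campanian	Cerro del Pueblo formation (Mexico)	72.5	89.32	st.
Juglandaceae	Cyclocarya brownii	Late Paleocene	Almont and Beicegel Creek (North Dakota, USA)	59.2	76.02	cr.
Rosales	unnamed Rosidae	Turonian	Raritan formation (New Jersey)	93.9	110.7	cr.
Betulaceae	Endressianthus miraensis	Campanian-Maastrichtian	Mira (Portugal)	72.1	88.92	cr.
Fagaceae	Antiquacupula sulcata	Late Santonian	Gaillard formation (Georgia, USA)	85.8	102.6	cr.
Salicaceae	Pseudosalix handleyi	Middle Eocene	Green River formation (Colorado-Utah, USA)	53.5	70.32	cr.
Ranunculales	Leefructus mirus	Barremanian-Aptian	Yixian formation (China)	125.0	141.8	cr.
Fabaceae	Fabaceae sp.	Early Eocene	Buchanan clay pit (Tenessee, USA)	56.0	72.82	cr.
Styracaceae	Rehderodendron stonei	Early Eocene	Sabals d'Anjou (France)	56.0	72.82	cr.
Dipterocarpaceae	Shorea maomingensis	Late Eocene	Huangniuling formation (Maoming Basin, China)	37.8	54.62	cr.
Lamiaceae	Ajuginucula smithii	Late Eocene-Early Oligocene	Bembridge Flora (UK)	33.9	50.72	cr.
Theaceae s.l.	Pentapetalum trifasciculandricus	Turonian	Raritan formation (New Jersey)	93.9	110.7	cr.
Myrsinaceae	unnamed Myrsinaceae	Middle Miocene	Foulden Hills Diatomite (New Zealand)	15.9	32.72	cr.
Myrtaceae	Tristaniandra alleyi	Middle Eocene	Golden Grove - East Yatala Sand Pit (South Australia)	47.8	64.62	cr.
Lythraceae	Decodon tiffneyi	Late Campanian	Cerro del Pueblo formation (Mexico)	72.5	89.32	cr.
Ampelocissus s.l.	Ampelocissus parvisemina	Late Paleocene	Beicegal Creek (North Dakota, USA)	59.2	76.02	cr.
Vitaceae	Indovitis chitaleyae	Maastrichtian	Mahurzari (India)	72.1	88.92	cr.
Rosa	Rosa germerensis	Early Eocene	Germer Basin Flora (Idaho, USA)	56.0	72.82	cr.
Prunus	Prunus wutuensis	Early Eocene	Wutu (China)	56.0	72.82	cr.
Myristicaceae	Myristicacarpum chandlerae	Early Eocene	London Clay (UK)	56.0	72.82	cr.
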