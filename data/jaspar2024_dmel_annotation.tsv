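motif_id	tf_name	path
MA0010.1	br	2.3.2
MA0010.2	br	2.3.2
MA0011.1	br	2.3.2
MA0011.2	br	2.3.2
MA0012.1	br	2.3.2
MA0012.2	br	2.3.2
MA0013.1	br	2.3.2
MA0015.1	Cf2	2.3.4
MA0015.2	Cf2	2.3.4
MA0016.1	usp	2.1.3
MA0016.2	usp	2.1.3
MA0022.1	dl	0.1
MA0023.1	dl	0.1
MA0026.1	Eip74EF	3.5.2
MA0049.1	hb	2.3.4
MA0085.1	Su(H)	0.2
MA0085.2	Su(H)	0.2
MA0086.1	sna	2.3.3
MA0086.2	sna	2.3.3
MA0086.3	sna	2.3.3
MA0094.1	Ubx	3.1.1
MA0094.2	Ubx	3.1.1
MA0094.3	Ubx	3.1.1
MA0126.1	ovo	2.3.3
MA0126.2	ovo	2.3.3
MA0165.1	Abd-B	3.1.1
MA0166.1	Antp	3.1.1
MA0167.1	Awh	3.1.5
MA0168.1	B-H1	3.1.1
MA0169.1	B-H2	3.1.1
MA0170.1	C15	3.1.2
MA0171.1	CG11085	3.1.2
MA0172.1	CG11294	3.1.3
MA0173.1	CG11617	3.1.4
MA0174.1	Dbx	3.1.0
MA0175.1	lms	3.1.2
MA0176.1	CG15696	3.1.2
MA0177.1	CG18599	3.1.2
MA0178.1	CG32105	3.1.5
MA0179.1	CG32532	3.1.3
MA0180.1	Vsx2	3.1.3
MA0181.1	Vsx1	3.1.3
MA0182.1	CG4328	3.1.5
MA0183.1	HHEX	3.1.2
MA0184.1	CG9876	3.1.3
MA0184.2	CG9876	3.1.3
MA0185.1	Deaf1	0.3
MA0185.2	Deaf1	0.3
MA0186.1	Dfd	3.1.1
MA0187.1	Dll	3.1.2
MA0188.1	Dr	3.1.2
MA0189.1	E5	3.1.2
MA0189.2	E5	3.1.2
MA0190.1	Gsc	3.1.3
MA0191.1	HGTX	3.1.2
MA0192.1	Hmx	3.1.2
MA0193.1	schlank	3.1.0
MA0194.1	Lim1	3.1.5
MA0195.1	Lim3	3.1.5
MA0195.2	Lim3	3.1.5
MA0196.1	NK7.1	3.1.2
MA0197.1	nub	3.1.10
MA0197.2	nub	3.1.10
MA0197.3	nub	3.1.10
MA0198.1	OdsH	3.1.3
MA0199.1	Optix	3.1.6
MA0200.1	Pph13	3.1.3
MA0200.2	Pph13	3.1.3
MA0201.1	Ptx1	3.1.3
MA0202.1	Rx	3.1.3
MA0203.1	Scr	3.1.1
MA0204.1	Six4	3.1.6
MA0205.1	Trl	2.3.3
MA0205.2	Trl	2.3.3
MA0205.3	Trl	2.3.3
MA0206.1	abd-A	3.1.1
MA0207.1	achi	3.1.4
MA0208.1	al	3.1.3
MA0209.1	ap	3.1.5
MA0210.1	ara	3.1.4
MA0211.1	bap	3.1.2
MA0212.1	bcd	3.1.3
MA0213.1	brk	0.2
MA0214.1	bsh	3.1.2
MA0215.1	btn	3.1.1
MA0216.1	cad	3.1.1
MA0216.2	cad	3.1.1
MA0217.1	caup	3.1.4
MA0218.1	ct	3.1.9
MA0219.1	ems	3.1.2
MA0220.1	en	3.1.2
MA0221.1	eve	3.1.1
MA0222.1	exd	3.1.4
MA0222.2	exd	3.1.4
MA0224.1	exex	3.1.1
MA0225.1	ftz	3.1.1
MA0226.1	hbn	3.1.3
MA0227.1	hth	3.1.4
MA0228.1	ind	3.1.1
MA0229.1	inv	3.1.2
MA0230.1	lab	3.1.1
MA0231.1	lbe	3.1.2
MA0232.1	lbl	3.1.2
MA0233.1	mirr	3.1.4
MA0234.1	oc	3.1.3
MA0235.1	onecut	3.1.9
MA0236.1	otp	3.1.3
MA0237.1	pan	0.4
MA0237.2	pan	0.4
MA0238.1	pb	3.1.1
MA0239.1	prd	0.5
MA0239.2	prd	0.5
MA0240.1	repo	3.1.3
MA0241.1	ro	3.1.1
MA0242.1	Bgb::run	0.6
MA0243.1	sd	0.7
MA0243.2	sd	0.7
MA0244.1	slbo	1.1.8
MA0245.1	slou	3.1.2
MA0246.1	so	3.1.6
MA0247.1	tin	3.1.0
MA0247.2	tin	3.1.0
MA0247.3	tin	3.1.0
MA0248.1	tup	3.1.5
MA0249.1	twi	1.2.3
MA0249.2	twi	1.2.3
MA0249.3	twi	1.2.3
MA0250.1	unc-4	3.1.3
MA0251.1	unpg	3.1.1
MA0252.1	vis	3.1.4
MA0252.2	vis	3.1.4
MA0253.1	vnd	3.1.2
MA0254.1	vvl	3.1.10
MA0255.1	z	0.2
MA0255.2	z	0.2
MA0256.1	zen	3.1.1
MA0257.1	zen2	3.1.1
MA0257.2	zen2	3.1.1
MA0443.1	btd	2.3.2
MA0443.2	btd	2.3.2
MA0444.1	CG34031	3.1.2
MA0445.1	D	0.4
MA0446.1	fkh	3.3.1
MA0447.1	gt	1.1.8
MA0448.1	H2.0	3.1.2
MA0449.1	h	0.8
MA0450.1	hkb	2.3.1
MA0451.1	kni	2.1.2
MA0451.2	kni	2.1.2
MA0452.1	Kr	2.3.3
MA0452.2	Kr	2.3.3
MA0452.3	Kr	2.3.3
MA0454.1	odd	2.3.3
MA0456.1	opa	2.3.3
MA0457.1	PHDP	3.1.3
MA0457.2	PHDP	3.1.3
MA0458.1	slp1	3.3.1
MA0458.2	slp1	3.3.1
MA0459.1	tll	2.1.3
MA0460.1	ttk	2.3.2
MA0529.1	BEAF-32	2.3.0
MA0529.2	BEAF-32	2.3.0
MA0529.3	BEAF-32	2.3.0
MA0530.1	cnc::maf-S	1.1.1
MA0530.2	cnc::maf-S	1.1.1
MA0531.1	CTCF	2.3.3
MA0531.2	CTCF	2.3.3
MA0532.1	Stat92E	0.9
MA0532.2	Stat92E	0.9
MA0533.1	su(Hw)	2.3.4
MA0534.1	EcR::usp	2.1.2
MA0535.1	Mad	0.10
MA0536.1	pnr	0.11
MA0536.2	pnr	0.11
MA0915.1	dve	3.1.9
MA0915.2	dve	3.1.9
MA0916.1	Ets21C	3.5.2
MA0917.1	gcm2	0.12
MA1455.1	dmrt99B	0.13
MA1455.2	dmrt99B	0.13
MA1456.1	Dref	2.3.5
MA1456.2	Dref	2.3.5
MA1457.1	grh	0.14
MA1457.2	grh	0.14
MA1458.1	Hsf	0.15
MA1458.2	Hsf	0.15
MA1459.1	M1BP	2.3.3
MA1459.2	M1BP	2.3.3
MA1460.1	pho	2.3.3
MA1460.2	pho	2.3.3
MA1461.1	sv	0.5
MA1461.2	sv	0.5
MA1462.1	vfl	2.3.3
MA1462.2	vfl	2.3.3
MA1700.1	Clamp	2.3.4
MA1702.1	Pdp1	1.1.8
MA1702.2	Pdp1	1.1.8
MA1836.1	dsx	0.13
MA1836.2	dsx	0.13
MA1837.1	Elba1	0.2
MA1837.2	Elba1	0.2
MA1838.1	Elba2	0.2
MA1838.2	Elba2	0.2
MA1839.1	GATAd	0.11
MA1839.2	GATAd	0.11
MA1840.1	gcm	0.12
MA1840.2	gcm	0.12
MA1841.1	kn	0.1
MA1841.2	kn	0.1
MA2107.1	cg	2.3.3
MA2108.1	sqz	2.3.3
MA2188.1	acj6	3.1.10
MA2189.1	Adf1	2.3.3
MA2190.1	Aef1	2.3.3
MA2191.1	amos	1.2.3
MA2192.1	Atf-2	1.1.1
MA2193.1	Atf3	1.1.2
MA2194.1	Atf6	1.1.1
MA2195.1	ato	1.2.3
MA2196.1	bigmax	1.2.6
MA2197.1	bin	3.3.1
MA2198.1	Blimp-1	2.3.3
MA2199.1	bowl	2.3.3
MA2200.1	bs	0.16
MA2201.1	Bteb2	2.3.1
MA2202.1	byn	0.17
MA2203.1	CG12605	2.3.3
MA2204.1	CG4360	2.3.3
MA2205.1	CG7928	2.3.3
MA2206.1	CHES-1-like	3.3.1
MA2207.1	ci	2.3.3
MA2208.1	crc	1.1.6
MA2209.1	CrebA	1.1.7
MA2210.1	CrebB	1.1.7
MA2211.1	croc	3.3.1
MA2212.1	dar1	2.3.1
MA2213.1	Dif	0.1
MA2214.1	dimm	1.2.3
MA2215.1	dm	1.2.6
MA2216.1	Doc2	0.17
MA2217.1	dpn	1.2.0
MA2218.1	dsf	2.1.3
MA2219.1	E(spl)m3-HLH	1.2.0
MA2220.1	E(spl)mbeta-HLH	1.2.0
MA2221.1	E(spl)mdelta-HLH	1.2.0
MA2222.1	E(spl)mgamma-HLH	1.2.0
MA2223.1	EcR	2.1.2
MA2224.1	Eip75B	2.1.2
MA2225.1	erm	2.3.3
MA2226.1	ERR	2.1.1
MA2227.1	esg	2.3.3
MA2228.1	Ets65A	3.5.2
MA2229.1	Ets96B	3.5.2
MA2230.1	Ets97D	3.5.2
MA2231.1	Ets98B	3.5.2
MA2232.1	fd59A	3.3.1
MA2233.1	Fer1	1.2.3
MA2234.1	Fer2	1.2.3
MA2235.1	FoxL1	3.3.1
MA2236.1	foxo	3.3.1
MA2237.1	FoxP	3.3.1
MA2238.1	GATAe	0.11
MA2239.1	gsb	0.5
MA2240.1	Hey	1.2.0
MA2241.1	HLH4C	1.2.3
MA2242.1	Hnf4	2.1.3
MA2243.1	Hr38	2.1.0
MA2244.1	Hr39	2.1.6
MA2245.1	Hr78	2.1.3
MA2246.1	Jra	1.1.1
MA2247.1	Kah	2.3.3
MA2248.1	kay	1.1.2
MA2249.1	ken	2.3.2
MA2250.1	klu	2.3.3
MA2251.1	knrl	2.1.2
MA2252.1	lmd	2.3.3
MA2253.1	luna	2.3.1
MA2254.1	lz	0.6
MA2255.1	Max	1.2.6
MA2256.1	mid	0.17
MA2257.1	Mitf	1.2.6
MA2258.1	Mnt	1.2.6
MA2259.1	org-1	0.17
MA2260.1	pdm3	3.1.10
MA2261.1	phol	2.3.3
MA2262.1	pnt	3.5.2
MA2263.1	Poxm	0.5
MA2264.1	Rel	0.1
MA2265.1	retn	0.18
MA2266.1	Rfx	3.3.3
MA2267.1	rib	2.3.2
MA2268.1	sage	3.1.4
MA2269.1	sc	1.2.0
MA2270.1	scrt	2.3.3
MA2271.1	sens	2.3.3
MA2272.1	slp2	3.3.1
MA2273.1	Sox102F	0.4
MA2274.1	Sox14	0.4
MA2275.1	Sox15	0.4
MA2276.1	Sox21a	0.4
MA2277.1	Sox21b	0.4
MA2278.1	SoxN	0.4
MA2279.1	Sp1	2.3.1
MA2280.1	Spps	2.3.1
MA2281.1	SREBP	1.2.6
MA2282.1	SREBP	1.2.6
MA2283.1	srp	0.11
MA2284.1	ss	1.2.5
MA2285.1	sug	2.3.3
MA2286.1	svp	2.1.3
MA2287.1	TfAP-2	0.19
MA2288.1	tj	1.1.3
MA2289.1	toy	0.5
MA2290.1	Usf	1.2.6
MA2291.1	vri	1.1.8
MA2292.1	wor	2.3.3
MA2293.1	Xbp1	1.1.5
MA2294.1	Xrp1	0.2
MA2295.1	ac	1.2.0
MA2296.1	aop	3.5.2
MA2297.1	BtbVII	2.3.3
MA2298.1	CG3065	2.3.1
MA2299.1	CG4854	2.3.3
MA2300.1	CG8319	2.3.3
MA2301.1	clk	1.2.5
MA2302.1	Crg-1	3.3.1
MA2303.1	crp	1.2.6
MA2304.1	cwo	1.2.0
MA2305.1	cyc	1.2.5
MA2306.1	D1	0.20
MA2307.1	D19B	2.3.3
MA2308.1	da	1.2.0
MA2309.1	ewg	1.1.1
MA2310.1	fru	2.3.4
MA2311.1	ftz-f1	2.1.0
MA2312.1	grn	0.11
MA2313.1	hng1	2.3.3
MA2314.1	hr3	2.1.2
MA2315.1	insv	0.2
MA2316.1	l(3)neo38	2.3.1
MA2317.1	nau	1.2.0
MA2318.1	pita	2.3.3
MA2319.1	run	0.6
MA2320.1	Sox100B	0.4
MA2321.1	tx	1.2.3
MA2322.1	ZIPIC	2.3.3
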