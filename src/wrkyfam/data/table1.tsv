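gene_name	orf_aa	group	conserved_motif	domain_pattern	best_hit_at_name	best_hit_locus	stress
DcWRKY1	598	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY2	318	III	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY70	AT3G56400.1	
DcWRKY3	566	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY4	436	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY5	287	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY48	AT5G49520.1	drought, salt
DcWRKY6	472	I	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY44	AT2G37260.2	
DcWRKY7	351	III	WRKYGQK	C-X_7_-C-X_23_-HXC	AtWRKY41	AT4G11070.1	
DcWRKY8	332	III	WRKYGQK	C-X_7_-C-X_23_-HXC	AtWRKY53	AT4G23810.1	drought
DcWRKY9	101	IId	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY15	AT2G23320.1	drought, salt
DcWRKY10	294	III	WRKYGQK	C-X_7_-C-X_22_-HXC	AtWRKY30	AT5G24110.1	drought, salt
DcWRKY11	175	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY75	AT5G13080.1	salt
DcWRKY12	332	IIe	WRKYGQK	C-X_5_-C-X_22_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY13	520	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY14	305	IIe	WRKYGQK	C-X_5_-C-X_22_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY15	514	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY4	AT1G13960.1	drought, salt
DcWRKY16	338	IId	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY21	AT2G30590.1	
DcWRKY17	242	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY24	AT5G41570.1	
DcWRKY18	311	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY19	204	IIc	WRKYGKK	C-X_4_-C-X_23_-HXH	AtWRKY51	AT5G64810.1	cold
DcWRKY20	346	IId	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY21	AT2G30590.1	
DcWRKY21	163	IIc	WRKYGKK	C-X_4_-C-X_23_-HXH	AtWRKY50	AT5G26170.1	
DcWRKY22	157	IIc	WRKYGKK	C-X_4_-C-X_23_-HXH	AtWRKY50	AT5G26170.1	
DcWRKY23	522	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY24	507	I	WRKYGQK	C-X_4_-C-X_22_-HXH(N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY33	AT2G38470.1	drought, salt
DcWRKY25	532	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY26	324	I	WRKYGQK	C-X_4_-C-X_22_-HXH(N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY3	AT2G03340.1	
DcWRKY27	691	I	WRKYGQK	C-X_4_-C-X_22_-HXH(N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY2	AT5G56270.1	heat
DcWRKY28	298	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY33	AT2G38470.1	drought, salt
DcWRKY29	233	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY20	AT1G29280.1	
DcWRKY30	551	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY33	AT2G38470.1	drought, salt
DcWRKY31	343	IIa	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY40	AT1G80840.1	drought, salt
DcWRKY32	390	III	WRKYGQK	C-X_7_-C-X_23_-HXC	AtWRKY30	AT5G24110.1	drought, salt
DcWRKY33	531	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY1	AT2G04880.2	
DcWRKY34	429	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY20	AT4G26640.1	
DcWRKY35	248	IId	WKKYDHK	C-X_5_-C-X_23_-HXH	AtWRKY7	AT4G24240.1	salt
DcWRKY36	397	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY14	AT1G30650.1	
DcWRKY37	250	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY13	AT4G39410.1	
DcWRKY38	305	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY71	AT1G29860.1	
DcWRKY39	179	IIa	WRKYGQK	C-X_5_-C-X_22_-HXH	AtWRKY40	AT1G80840.1	drought, salt
DcWRKY40	219	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY65	AT1G29280.1	
DcWRKY41	336	III	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY41	AT4G11070.1	
DcWRKY42	300	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY43	306	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY71	AT1G29860.1	
DcWRKY44	187	IIa	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY40	AT1G80840.1	drought, salt
DcWRKY45	278	IIa	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY71	AT1G80840.1	drought, salt
DcWRKY46	337	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY33	AT2G38470.1	drought, salt
DcWRKY47	216	III	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY70	AT3G56400.1	
DcWRKY48	198	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY43	AT2G46130.1	
DcWRKY49	442	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY72	AT5G15130.1	
DcWRKY50	302	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY72	AT5G15130.1	
DcWRKY51	539	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY61	AT1G18860.1	
DcWRKY52	236	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY69	AT3G58710.1	
DcWRKY53	227	IIc	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY28	AT4G18170.1	cold, drought, salt
DcWRKY54	287	IIc	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY57	AT1G69310.2	
DcWRKY55	313	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY56	442	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY35	AT2G34830.1	
DcWRKY57	287	IIc	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY57	AT1G69310.2	
DcWRKY58	313	IId	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY15	AT2G23320.1	drought, salt
DcWRKY59	330	I	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY33	AT2G38470.1	drought, salt
DcWRKY60	324	IId	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY7	AT4G24240.1	salt
DcWRKY61	241	III	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY55	AT2G40740.1	
DcWRKY62	250	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY35	AT2G34830.1	
DcWRKY63	172	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY65	AT1G29280.1	
DcWRKY64	555	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY6	AT1G62300.1	cold, drought, salt
DcWRKY65	560	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY20	AT4G26640.2	
DcWRKY66	248	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY65	AT1G29280.1	
DcWRKY67	514	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY4	AT1G13960.1	drought, salt
DcWRKY68	507	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY33	AT2G38470.1	drought, salt
DcWRKY69	343	III	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY70	AT3G56400.1	
DcWRKY70	698	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY2	AT5G56270.1	heat
DcWRKY71	332	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY23	AT2G47260.1	
DcWRKY72	189	IIc	WRKYGKK	C-X_4_-C-X_23_-HXH	AtWRKY51	AT5G64810.1	cold
DcWRKY73	250	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY65	AT1G29280.1	
DcWRKY74	318	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY75	286	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY65	AT1G29280.1	
DcWRKY76	254	IId	WKKYDHK	C-X_5_-C-X_23_-HXH	AtWRKY7	AT4G24240.1	salt
DcWRKY77	233	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY65	AT1G29280.1	
DcWRKY78	260	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY69	AT3G58710.2	
DcWRKY79	302	IIb	WRKYGQK	C-X_5_-C-X_22_-HXH	AtWRKY72	AT5G15130.1	
DcWRKY80	278	IIa	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY40	AT1G80840.1	drought, salt
DcWRKY81	324	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY3	AT2G03340.1	
DcWRKY82	287	IIc	WRKYGQK	C-X_4_-C-X_22_-HXH	AtWRKY48	AT5G49520.1	drought, salt
DcWRKY83	175	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY69	AT3G58710.1	
DcWRKY84	311	IIe	WRKYGQK	C-X_5_-C-X_24_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY85	310	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY72	AT5G15130.1	
DcWRKY86	338	III	WRKYGQK	C-X_7_-C-X_23_-HTC	AtWRKY41	AT4G23810.1	
DcWRKY87	276	IId	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY11	AT4G31550.2	drought
DcWRKY88	297	IId	WKKYDQK	C-X_5_-C-X_23_-HXH	AtWRKY11	AT4G31550.1	drought
DcWRKY89	865	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY61	AT1G18860.1	
DcWRKY90	282	IIe	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY22	AT4G01250.1	drought, salt
DcWRKY91	287	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY57	AT1G69310.2	
DcWRKY92	294	III	WRKYGQK	C-X_7_-C-X_23_-HXH	AtWRKY49	AT5G43290.1	
DcWRKY93	539	I	WRKYGQK	C-X_4_-C-X_22_-HXH (N)/C-X_4_-C-X_23_-HXH (C)	AtWRKY1	AT2G04880.2	
DcWRKY94	480	IIb	WRKYGQK	C-X_5_-C-X_23_-HXH	AtWRKY9	AT1G68150.1	
DcWRKY95	184	IIc	WRKYGQK	C-X_4_-C-X_23_-HXH	AtWRKY75	AT5G13080.1	salt
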