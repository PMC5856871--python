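compound_id	name	formula	monoisotopic_mass	source
CPD0001	Water	H2O	18.010565	custom
CPD0002	Glucose	C6H12O6	180.063388	hmdb
CPD0003	Alanine	C3H7NO2	89.047678	hmdb
CPD0004	Palmitic acid	C16H32O2	256.240230	lipidmaps
CPD0005	Cholesterol	C27H46O	386.354866	lipidmaps
CPD0006	Glycine	C2H5NO2	75.032028	hmdb
CPD0007	Serine	C3H7NO3	105.042593	hmdb
CPD0008	Proline	C5H9NO2	115.063329	hmdb
CPD0009	Valine	C5H11NO2	117.078979	hmdb
CPD0010	Threonine	C4H9NO3	119.058243	hmdb
CPD0011	Leucine	C6H13NO2	131.094629	hmdb
CPD0012	Aspartic acid	C4H7NO4	133.037508	hmdb
CPD0013	Glutamine	C5H10N2O3	146.069142	hmdb
CPD0014	Lysine	C6H14N2O2	146.105528	hmdb
CPD0015	Glutamic acid	C5H9NO4	147.053158	hmdb
CPD0016	Methionine	C5H11NO2S	149.051050	hmdb
CPD0017	Histidine	C6H9N3O2	155.069477	hmdb
CPD0018	Phenylalanine	C9H11NO2	165.078979	hmdb
CPD0019	Arginine	C6H14N4O2	174.111676	hmdb
CPD0020	Tyrosine	C9H11NO3	181.073893	hmdb
CPD0021	Tryptophan	C11H12N2O2	204.089878	hmdb
CPD0022	Citric acid	C6H8O7	192.027003	hmdb
CPD0023	Lactic acid	C3H6O3	90.031694	hmdb
CPD0024	Pyruvic acid	C3H4O3	88.016044	hmdb
CPD0025	Succinic acid	C4H6O4	118.026609	hmdb
CPD0026	Fumaric acid	C4H4O4	116.010959	hmdb
CPD0027	Malic acid	C4H6O5	134.021523	hmdb
CPD0028	Alpha-ketoglutaric acid	C5H6O5	146.021523	hmdb
CPD0029	Oxaloacetic acid	C4H4O5	132.005873	hmdb
CPD0030	Creatinine	C4H7N3O	113.058912	hmdb
CPD0031	Creatine	C4H9N3O2	131.069477	hmdb
CPD0032	Uric acid	C5H4N4O3	168.028340	hmdb
CPD0033	Hypoxanthine	C5H4N4O	136.038511	hmdb
CPD0034	Xanthine	C5H4N4O2	152.033425	hmdb
CPD0035	Adenine	C5H5N5	135.054495	hmdb
CPD0036	Adenosine	C10H13N5O4	267.096754	hmdb
CPD0037	Inosine	C10H12N4O5	268.080770	hmdb
CPD0038	Uridine	C9H12N2O6	244.069536	hmdb
CPD0039	Caffeine	C8H10N4O2	194.080376	hmdb
CPD0040	Taurine	C2H7NO3S	125.014664	hmdb
CPD0041	Carnitine	C7H15NO3	161.105193	hmdb
CPD0042	Acetylcarnitine	C9H17NO4	203.115758	hmdb
CPD0043	Choline	C5H13NO	103.099714	hmdb
CPD0044	Betaine	C5H11NO2	117.078979	hmdb
CPD0045	Stearic acid	C18H36O2	284.271530	lipidmaps
CPD0046	Oleic acid	C18H34O2	282.255880	lipidmaps
CPD0047	Linoleic acid	C18H32O2	280.240230	lipidmaps
CPD0048	Arachidonic acid	C20H32O2	304.240230	lipidmaps
CPD0049	LPC 16:0	C24H50NO7P	495.332490	lipidmaps
CPD0050	PC 34:1	C42H82NO8P	759.577805	lipidmaps
CPD0051	Sphingosine	C18H37NO2	299.282429	lipidmaps
CPD0052	Cortisol	C21H30O5	362.209324	hmdb
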