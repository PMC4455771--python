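# JTT amino-acid replacement model (Jones, Taylor & Thornton 1992),
# lower-triangular symmetric exchangeabilities in the order
# A R N D C Q E G H I L K M F P S T W Y V, followed by the model's
# published equilibrium amino-acid frequencies.
58.0
54.0	81.0
56.0	57.0	105.0
179.0	27.0	36.0	30.0
35.0	54.0	15.0	194.0	378.0
475.0	9.0	11.0	298.0	45.0	16.0
113.0	310.0	29.0	137.0	328.0	22.0	38.0
646.0	44.0	5.0	74.0	101.0	64.0	126.0	20.0
17.0	528.0	34.0	86.0	58.0	81.0	391.0	47.0	12.0
263.0	30.0	10.0	15.0	503.0	232.0	8.0	70.0	16.0	10.0
49.0	767.0	130.0	112.0	11.0	7.0	26.0	15.0	4.0	15.0	59.0
38.0	4.0	46.0	31.0	9.0	5.0	59.0	69.0	17.0	23.0	7.0	31.0
78.0	14.0	223.0	42.0	115.0	209.0	62.0	323.0	26.0	597.0	9.0	72.0	292.0
43.0	4.0	164.0	53.0	51.0	18.0	24.0	20.0	119.0	26.0	12.0	9.0	181.0	18.0
5.0	18.0	30.0	32.0	10.0	7.0	45.0	23.0	6.0	6.0	27.0	14.0	5.0	24.0	201.0
33.0	55.0	8.0	47.0	16.0	56.0	45.0	33.0	40.0	115.0	73.0	46.0	8.0	573.0	11.0	229.0
21.0	479.0	89.0	10.0	40.0	245.0	9.0	32.0	961.0	14.0	388.0	248.0	102.0	59.0	25.0	52.0	24.0
180.0	65.0	4.0	21.0	47.0	103.0	10.0	8.0	14.0	43.0	16.0	29.0	226.0	24.0	18.0	323.0	17.0	92.0
12.0	53.0	536.0	62.0	285.0	118.0	6.0	10.0	23.0	477.0	35.0	63.0	38.0	12.0	21.0	112.0	71.0	25.0	16.0
0.0767479232521	0.0516909483091	0.042644957355	0.0515439484561	0.019802980197	0.040751959248	0.0618299381701	0.0731519268481	0.022943977056	0.0537609462391	0.0919039080961	0.0586759413241	0.023825976174	0.040125959874	0.0509009490991	0.0687649312351	0.0585649414351	0.014260985739	0.032101967898	0.0660049339951
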