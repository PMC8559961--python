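gene_id	label	gene_class	hypotheses	chrom	start	end
CYP325T2	CYP325T2	CYP	H1	2	50000000	50030000
CYP9J24	CYP9J24	CYP	H1	3	290000000	290030000
AAEL026582	CYP6AA6	CYP	H2,H3	1	270000000	270030000
AAEL014893	CYP6BB2	CYP	H2,H3	1	270070000	270100000
AAEL003748	CYP9AE1	CYP	H2,H3	1	100000000	100030000
AAEL014614	CYP9J10	CYP	H2,H3	3	285000000	285030000
AAEL006784	CYP9J17	CYP	H2,H3	3	287000000	287030000
AAEL014609	CYP9J26	CYP	H2,H3	3	280000000	280030000
AAEL026665	CYP9J27	CYP	H2,H3	3	280050000	280080000
AAEL014617	CYP9J28	CYP	H2,H3	3	280100000	280130000
AAEL025530	CYP9M5	CYP	H2,H3	3	283000000	283030000
AAEL001312	CYP9M6	CYP	H2,H3	3	283060000	283090000
AAEL009018	CYP6CB1	CYP	H6	3	288000000	288030000
AAEL014618	CYP9J18	CYP	H6	3	288400000	288430000
AAEL028635	CYP9J19	CYP	H6	3	288800000	288830000
AAEL014619	CYP9J22	CYP	H6	3	289200000	289230000
AAEL006805	CYP9J2	CYP	H6	3	289600000	289630000
AAEL0001459		TF	H5	1	45000000	45030000
AAEL0002896		TF	H5	1	47000000	47030000
AAEL0003176		TF	H5	1	49000000	49030000
AAEL0003506		TF	H5	1	51000000	51030000
AAEL0004130		TF	H5	2	20000000	20030000
AAEL0004669		TF	H5	2	23000000	23030000
AAEL0005247		TF	H5	1	53000000	53030000
AAEL0005602		TF	H4,H5	1	55000000	55030000
AAEL0005606		TF	H5	1	57000000	57030000
AAEL0006032		TF	H4	1	59000000	59030000
AAEL0006035		TF	H4	1	61000000	61030000
AAEL0006197		TF	H5	1	63000000	63030000
AAEL0006206		lncRNA	H5	2	26000000	26030000
AAEL0006597		TF	H4	1	65000000	65030000
AAEL0006932		TF	H5	2	29000000	29030000
AAEL0007970		lncRNA	H5	2	32000000	32030000
AAEL0007988		TF	H4	2	35000000	35030000
AAEL0008401		TF	H5	1	67000000	67030000
AAEL0010576		TF	H4	1	69000000	69030000
AAEL0011160		TF	H5	2	38000000	38030000
AAEL0012628		TF	H5	2	41000000	41030000
AAEL0012990		TF	H5	2	44000000	44030000
AAEL0013562		TF	H4	2	47000000	47030000
AAEL0013760		TF	H4	1	71000000	71030000
AAEL0014406		TF	H5	1	73000000	73030000
AAEL0018695		TF	H4	1	75000000	75030000
AAEL0019560		TF	H4	1	77000000	77030000
AAEL0019765		TF	H5	2	50000000	50030000
AAEL0019809		TF	H5	1	79000000	79030000
AAEL0019840		TF	H4	1	81000000	81030000
AAEL0019968		TF	H5	1	83000000	83030000
AAEL0020179		lncRNA	H5	NIGP0100179	500000	530000
AAEL0020308		lncRNA	H5	2	53000000	53030000
AAEL0020350		lncRNA	H5	1	85000000	85030000
AAEL0020445		lncRNA	H5	2	56000000	56030000
AAEL0020459		TF	H5	1	87000000	87030000
AAEL0020507		lncRNA	H5	2	59000000	59030000
AAEL0020816		lncRNA	H5	1	89000000	89030000
AAEL0020844		lncRNA	H5	2	62000000	62030000
AAEL0021107		lncRNA	H5	2	65000000	65030000
AAEL0021117		lncRNA	H5	1	91000000	91030000
AAEL0021124		lncRNA	H5	2	68000000	68030000
AAEL0021188		lncRNA	H5	2	71000000	71030000
AAEL0021207		lncRNA	H5	2	74000000	74030000
AAEL0021235		TF	H5	1	93000000	93030000
AAEL0021303		TF	H4,H5	1	95000000	95030000
AAEL0021326		lncRNA	H5	2	77000000	77030000
AAEL0021614		lncRNA	H5	1	97000000	97030000
AAEL0021658		lncRNA	H5	1	99000000	99030000
AAEL0021758		lncRNA	H5	NIGP0101758	500000	530000
AAEL0021796		lncRNA	H5	1	101000000	101030000
AAEL0021877		TF	H4	1	103000000	103030000
AAEL0021901		lncRNA	H5	1	105000000	105030000
AAEL0021935		lncRNA	H5	2	80000000	80030000
AAEL0021952		TF	H5	1	107000000	107030000
AAEL0021984		lncRNA	H5	2	83000000	83030000
AAEL0022024		lncRNA	H5	2	86000000	86030000
AAEL0022110		lncRNA	H5	2	89000000	89030000
AAEL0022135		TF	H4	2	92000000	92030000
AAEL0022195		TF	H4	1	109000000	109030000
AAEL0022278		lncRNA	H5	NIGP0102278	500000	530000
AAEL0022402		TF	H5	2	95000000	95030000
AAEL0022636		lncRNA	H5	2	98000000	98030000
AAEL0022706		lncRNA	H5	1	111000000	111030000
AAEL0022711		lncRNA	H5	1	113000000	113030000
AAEL0023156		lncRNA	H5	1	115000000	115030000
AAEL0023170		lncRNA	H5	2	101000000	101030000
AAEL0023172		lncRNA	H5	2	104000000	104030000
AAEL0023265		TF	H5	1	117000000	117030000
AAEL0023302		lncRNA	H5	2	107000000	107030000
AAEL0023306		lncRNA	H5	1	119000000	119030000
AAEL0023405		lncRNA	H5	2	110000000	110030000
AAEL0023428		lncRNA	H5	2	113000000	113030000
AAEL0023574		TF	H4	1	121000000	121030000
AAEL0023707		lncRNA	H5	2	116000000	116030000
AAEL0023795		lncRNA	H5	NIGP0103795	500000	530000
AAEL0023842		TF	H4	NIGP0103842	500000	530000
AAEL0023937		lncRNA	H5	2	119000000	119030000
AAEL0024060		lncRNA	H5	2	122000000	122030000
AAEL0024161		lncRNA	H5	2	125000000	125030000
AAEL0024318		lncRNA	H5	2	128000000	128030000
AAEL0024523		lncRNA	H5	NIGP0104523	500000	530000
AAEL0024603		lncRNA	H5	1	123000000	123030000
AAEL0024640		lncRNA	H5	1	125000000	125030000
AAEL0024782		lncRNA	H5	1	127000000	127030000
AAEL0024864		lncRNA	H5	1	129000000	129030000
AAEL0024869		lncRNA	H5	1	131000000	131030000
AAEL0024872		lncRNA	H5	2	131000000	131030000
AAEL0024949		lncRNA	H5	2	134000000	134030000
AAEL0024959		lncRNA	H5	2	137000000	137030000
AAEL0025193		lncRNA	H5	2	140000000	140030000
AAEL0025264		lncRNA	H5	2	143000000	143030000
AAEL0025336		TF	H4	NIGP0105336	500000	530000
AAEL0025399		lncRNA	H5	2	146000000	146030000
AAEL0025559		lncRNA	H5	2	149000000	149030000
AAEL0025618		lncRNA	H5	1	133000000	133030000
AAEL0025640		lncRNA	H5	NIGP0105640	500000	530000
AAEL0025853		lncRNA	H5	2	152000000	152030000
AAEL0025854		lncRNA	H5	2	155000000	155030000
AAEL0025912		lncRNA	H5	2	158000000	158030000
AAEL0026107		lncRNA	H5	1	135000000	135030000
AAEL0026208		lncRNA	H5	2	161000000	161030000
AAEL0026242		lncRNA	H5	1	137000000	137030000
AAEL0026527		lncRNA	H5	1	139000000	139030000
AAEL0026574		TF	H5	1	141000000	141030000
AAEL0026672		TF	H4	1	143000000	143030000
AAEL0026769		lncRNA	H5	2	164000000	164030000
AAEL0026784		lncRNA	H5	1	145000000	145030000
AAEL0026801		lncRNA	H5	2	167000000	167030000
AAEL0026917		TF	H5	2	170000000	170030000
AAEL0026933		TF	H4	1	147000000	147030000
AAEL0027182		lncRNA	H5	2	173000000	173030000
AAEL0027227		lncRNA	H5	1	149000000	149030000
AAEL0027357		lncRNA	H5	1	151000000	151030000
AAEL0027461		lncRNA	H5	1	153000000	153030000
AAEL0027939		lncRNA	H5	2	176000000	176030000
AAEL0027946		lncRNA	H5	2	179000000	179030000
AAEL0028025		TF	H4	1	155000000	155030000
AAEL0028112		TF	H4	1	157000000	157030000
AAEL0028157		TF	H4	2	182000000	182030000
AAEL0028219		lncRNA	H5	2	185000000	185030000
AAEL0028241		lncRNA	H5	2	188000000	188030000
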