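name	total_reads	rpm
mir-21	2318344	338603.3
let-7f-2//let-7f-1	1073705	156818.9
mir-126	1014272	148138.4
let-7a-1//let-7a-2//let-7a-3	387336	56572.0
mir-378//mir-378-2	340689	49759.0
mir-24-2	258546	37761.7
mir-103-1//mir-103-2	148228	21649.3
mir-30a	112865	16484.4
mir-27b	104682	15289.2
let-7g	66479	9709.5
mir-452	61833	9031.0
mir-30d	61224	8942.0
mir-151	60052	8770.8
mir-140	55008	8034.1
mir-20a	48329	7058.6
mir-23a	45707	6675.7
mir-17	45449	6638.0
let-7b	34754	5076.0
mir-148b	33677	4918.7
mir-26a-2//mir-26a-1	30576	4465.7
mir-191	27688	4043.9
mir-93	27177	3969.3
mir-184	25142	3672.1
mir-186	25078	3662.7
let-7e	21635	3159.9
mir-29a	21407	3126.6
mir-152	20604	3009.3
mir-30e	19696	2876.7
mir-101//mir-101-1	19218	2806.9
let-7i	18731	2735.7
mir-423	16993	2481.9
mir-28	15266	2229.7
mir-155	14390	2101.7
let-7c	14020	2047.7
mir-143	12204	1782.4
mir-181a-2//mir-181a-1	11882	1735.4
mir-146a	10952	1599.6
mir-15a	9938	1451.5
mir-99b	9755	1424.8
mir-148a	9502	1387.8
mir-125b-1//mir-125b-2	9395	1372.2
mir-106b	9284	1356.0
mir-26b	9146	1335.8
mir-16b	8750	1278.0
let-7d	8273	1208.3
mir-16a	8007	1169.5
mir-92//mir-92a	7427	1084.7
mir-7//mir-7-2//mir-7-1	6852	1000.8
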