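knockdown	annotation	max_fold_change
siELOVL1	Ceramide – 32:1:2 (C14:0 Cer)	1.7 (72 h)
siELOVL1	Ceramide – 34:1:2 (C16:0 Cer)	1.7 (48 h)
siELOVL1	Ceramide – 34:2:2 (C16:1 Cer)	1.5 (72 h)
siELOVL1	Ceramide – 38:1:2 (C20:0 Cer)	8.3 (72 h)
siELOVL1	Ceramide – 40:1:2 (C22:0 Cer)	1.3 (72 h)
siELOVL1	Ceramide – 40:2:2 (C22:1 Cer)	1.7 (72 h)
siELOVL1	Hexosylceramide – 34:1:2 (C16:0 HexCer)	1.5 (72 h)
siELOVL1	Hexosylceramide – 36:1:2 (C18:0 HexCer)	Accumulated (48 and 72 h)
siELOVL1	Hexosylceramide – 38:1:2 (C20:0 HexCer)	Accumulated (48 and 72 h)
siELOVL1	Hexosylceramide – 40:1:2 (C22:0 HexCer)	3 (72 h)
siELOVL1	Hexosylceramide – 40:2:2 (C22:1 HexCer)	Accumulated (48 and 72 h)
siELOVL1	Phosphatidylcholine – 17:0:0;17:1:0	3.7 (48 h)
siELOVL1	Phosphatidylcholine – 18:0:0;18:1:0	1.1 (72 h)
siELOVL1	Phosphatidylcholine – 18:0:0;18:2:0	2 (72 h)
siELOVL1	Phosphatidylcholine – 18:1:0;18:1:0	1.2 (72 h)
siELOVL1	Phosphatidylcholine – 18:1:0;18:2:0	1.1 (48 h)
siELOVL1	Phosphatidylcholine – 18:2:0;18:2:0	1.3 (48 h)
siELOVL1	Phosphatidylethanolamine ether – 18:1:0;18:1:0	1.05 (48 h)
siELOVL1	Phosphatidylethanolamine ether – 18:1:0;20:3:0	1.2 (72 h)
siELOVL1	Phosphatidylethanolamine ether – 18:1:0;20:4:0	1.2 (72 h)
siELOVL1	Phosphatidylinositol – 16:1:0;20:4:0	Accumulated (48 h)
siELOVL1	Phosphatidylserine – 14:0:0;18:1:0	1.8 (48 h)
siELOVL1	Phosphatidylserine – 16:1:0;20:0:0	3.2 (48 h)
siELOVL1	Phosphatidylserine – 18:1:0;20:0:0	1.9 (48 h)
siELOVL1	Phosphatidylserine – 18:2:0;20:0:0	Accumulated (48 h)
siELOVL1	Phosphatidylserine – 18:2:0;22:1:0	3.7 (72 h)
siSLC27A1	Hexosylceramide – 42:2:2 (C24:1 HexCer)	1.1 (72 h)
siSLC27A1	Phosphatidic acid – 16:0:0;18:2:0	3.2 (48 h)
siSLC27A1	Phosphatidylcholine – 16:1:0;16:1:0	1.1 (48 h)
siSLC27A1	Phosphatidylcholine – 18:0:0;20:3:0	1.3 (48 h)
siSLC27A1	Phosphatidylcholine ether – 16:1:0;16:1:0	1.2 (72 h)
siSLC27A1	Phosphatidylcholine ether – 16:1:0;20:4:0	4.2 (72 h)
siSLC27A1	Phosphatidylcholine ether – 18:1:0;16:1:0	1.3 (72 h)
siSLC27A1	Phosphatidylcholine ether – 18:1:0;20:4:0	1.1 (72 h)
siSLC27A1	Phosphatidylethanolamine ether – 16:1:0;20:3:0	1.1 (72 h)
siSLC27A1	Phosphatidylglycerol – 16:1:0;18:0:0	Accumulated (48 h)
siSLC27A1	Phosphatidylglycerol – 18:2:0;18:2:0	2.4 (72 h)
siSLC27A1	Phosphatidylglycerol – 18:2:0;20:3:0	7 (72 h)
siSLC27A1	Phosphatidylinositol – 16:2:0;18:0:0	Accumulated (48 h)
siSLC27A1	Phosphatidylinositol – 18:2:0;20:2:0	4 (48 h)
siSLC27A1	Phosphatidylserine – 16:1:0;18:1:0	1.3 (48 h)
siSLC27A1	Phosphatidylserine – 18:0:0;19:1:0	Accumulated (48 h)
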