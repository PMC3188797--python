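chrI	800	900	90.0
chrI	900	1000	91.0
chrI	1000	1100	92.0
chrI	1100	1200	93.0
chrI	1400	1500	94.0
chrI	1500	1600	95.0
chrI	1600	1700	96.0
chrI	1700	1800	97.0
chrI	3700	3800	85.0
chrI	3600	3700	86.0
chrI	3500	3600	87.0
chrI	3400	3500	88.0
chrI	3100	3200	89.0
chrI	3000	3100	90.0
chrI	2900	3000	91.0
chrI	2800	2900	92.0
chrI	4800	4900	80.0
chrI	4900	5000	81.0
chrI	5000	5100	82.0
chrI	5100	5200	83.0
chrI	5400	5500	84.0
chrI	5500	5600	85.0
chrI	5600	5700	86.0
chrI	5700	5800	87.0
chrI	7700	7800	75.0
chrI	7600	7700	76.0
chrI	7500	7600	77.0
chrI	7400	7500	78.0
chrI	7100	7200	79.0
chrI	7000	7100	80.0
chrI	6900	7000	81.0
chrI	6800	6900	82.0
chrI	8800	8900	70.0
chrI	8900	9000	71.0
chrI	9000	9100	72.0
chrI	9100	9200	73.0
chrI	9400	9500	74.0
chrI	9500	9600	75.0
chrI	9600	9700	76.0
chrI	9700	9800	77.0
chrI	11700	11800	65.0
chrI	11600	11700	66.0
chrI	11500	11600	67.0
chrI	11400	11500	68.0
chrI	11100	11200	69.0
chrI	11000	11100	70.0
chrI	10900	11000	71.0
chrI	10800	10900	72.0
chrI	12800	12900	60.0
chrI	12900	13000	61.0
chrI	13000	13100	62.0
chrI	13100	13200	63.0
chrI	13400	13500	64.0
chrI	13500	13600	65.0
chrI	13600	13700	66.0
chrI	13700	13800	67.0
chrI	15700	15800	55.0
chrI	15600	15700	56.0
chrI	15500	15600	57.0
chrI	15400	15500	58.0
chrI	15100	15200	59.0
chrI	15000	15100	60.0
chrI	14900	15000	61.0
chrI	14800	14900	62.0
chrI	16800	16900	50.0
chrI	16900	17000	51.0
chrI	17000	17100	52.0
chrI	17100	17200	53.0
chrI	17400	17500	54.0
chrI	17500	17600	55.0
chrI	17600	17700	56.0
chrI	17700	17800	57.0
chrI	19700	19800	45.0
chrI	19600	19700	46.0
chrI	19500	19600	47.0
chrI	19400	19500	48.0
chrI	19100	19200	49.0
chrI	19000	19100	50.0
chrI	18900	19000	51.0
chrI	18800	18900	52.0
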