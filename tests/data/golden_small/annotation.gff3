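##gff-version 3
chrI	chromexpress	mRNA	1001	1600	.	+	.	ID=t00;Parent=g00
chrI	chromexpress	mRNA	3001	3600	.	-	.	ID=t01;Parent=g01
chrI	chromexpress	mRNA	5001	5600	.	+	.	ID=t02;Parent=g02
chrI	chromexpress	mRNA	7001	7600	.	-	.	ID=t03;Parent=g03
chrI	chromexpress	mRNA	9001	9600	.	+	.	ID=t04;Parent=g04
chrI	chromexpress	mRNA	11001	11600	.	-	.	ID=t05;Parent=g05
chrI	chromexpress	mRNA	13001	13600	.	+	.	ID=t06;Parent=g06
chrI	chromexpress	mRNA	15001	15600	.	-	.	ID=t07;Parent=g07
chrI	chromexpress	mRNA	17001	17600	.	+	.	ID=t08;Parent=g08
chrI	chromexpress	mRNA	19001	19600	.	-	.	ID=t09;Parent=g09
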