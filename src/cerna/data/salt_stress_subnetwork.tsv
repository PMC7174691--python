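lncrna	mirna	mrna	subnetwork
lncRNA13472	sbi-MIR169b-p3	SORBI_3010G218400	tolerant
lncRNA11310	sbi-MIR5567-p3-2ss16CT17TC	SORBI_3001G158100	tolerant
lncRNA11310	sbi-MIR5567-p3-2ss16CT17TC	SORBI_3001G223100	tolerant
lncRNA11310	sbi-MIR5567-p3-2ss16CT17TC	SORBI_3002G237000	tolerant
lncRNA11310	sbi-MIR5567-p3-2ss16CT17TC	SORBI_3002G302000	tolerant
lncRNA11310	sbi-MIR5567-p3-2ss16CT17TC	SORBI_3003G327000	tolerant
lncRNA11310	sbi-MIR5567-p3-2ss16CT17TC	SORBI_3009G182800	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3001G158100	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3001G223100	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3002G237000	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3002G302000	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3003G327000	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3004G116300	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3004G302400	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3006G123500	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3007G046900	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3009G182800	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3009G208000	tolerant
lncRNA2846	sbi-MIR5567-p5-2	SORBI_3010G081800	tolerant
lncRNA26929	sbi-MIR5567-p5-2ss17CT18TC	SORBI_3001G158100	sensitive
lncRNA26929	sbi-MIR5567-p5-2ss17CT18TC	SORBI_3001G223100	sensitive
lncRNA26929	sbi-MIR5567-p5-2ss17CT18TC	SORBI_3003G327000	sensitive
lncRNA14798	PC-3p-270284-34	SORBI_3009G042700	sensitive
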