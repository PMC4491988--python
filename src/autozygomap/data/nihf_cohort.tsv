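family	gene	transcript	cdna	protein	csq	polyphen	sift	chrom	pos	ref	alt
14DG1727	GUSB	NM_000181	c.307C>T	p.R103W	missense	1.0	0.0	7	65425307	C	T
14DG1819	GUSB	NM_000181	c.1586A>G	p.Y529C	missense	1.0	0.0	7	65426586	A	G
10DG0827	CHRNA1	NM_001039523	c.762C>T	p.R254C	missense	1.0	0.0	2	175612762	C	T
09DG01201	PIGC	NM_002642	c.659T>C	p.L220P	missense	0.998	0.01	1	172400659	T	C
12DG2262	UBN1	NM_016936	c.2356T>A	p.L786M	missense	0.915	0.02	16	4902356	T	A
13DG0042	GUSB	NM_000181	c.1144C>T	p.R382C	missense	0.995	0.0	7	65426144	C	T
13DG0259
13DG0447	DNAH14	NM_001373	c.3755T>A	p.M1252K	missense	0.805	0.0	1	225123755	T	A
13DG0806	THSD1	NM_018676	c.617G>A	p.C206Y	missense	0.999	0.0	13	52950617	G	A
13DG0975	NEB	NM_001164507	c.21076C>T	p.R7026X	stopgain			2	152361076	C	T
13DG1635	CTSA	NM_000308	c.649delC	p.L217fs	frameshift			20	44520649	AC	A
13DG1885	MYOM1	NM_003803	c.4987G>A	p.V1663M	missense	0.999	0.0	18	3070987	G	A
13DG2155	GUSB	NM_000181	c.398G>C	p.W133S	missense	0.984	0.0	7	65425398	G	C
14DG0052	FZD6	NM_001164616	c.773A>G	p.Y258C	missense	1.0	0.0	8	104310773	A	G
14DG0946	THSD1	NM_018676	c.617G>A	p.C206Y	missense	0.999	0.0	13	52950617	G	A
14DG0947	GUSB	NM_000181	c.1069C>T	p.R357X	stopgain			7	65426069	C	T
14DG1037	GALNT14	NM_024572	c.1273C>T	p.R425X	stopgain			2	31131273	C	T
14DG1695	THSD1	NM_018676	c.617G>A	p.C206Y	missense	0.999	0.0	13	52950617	G	A
14DG1738	THSD1	NM_018676	c.670G>A	p.R224X	stopgain			13	52950670	G	A
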