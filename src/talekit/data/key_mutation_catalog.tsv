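category	strain	il	region	position	mutation_type	description	function	count
combined	MG	B,E	mdtJ/tqsA	-56/-237	DEL	Intergenic (-56/-237) Δ120 bp	Transporter	23
combined	DH1	B	tqsA/mdtJ	-239/-54	DEL	Intergenic (-239/-54) Δ120 bp	Transporter	5
combined	MG	B	tqsA	857-868/1035	DEL	Coding (857-868/1035 nt) Δ12 bp	Transporter	6
combined	DH1	B	pntA–tqsA	span	DEL	Δ3035 bp	Transhydrogenase/transporter	2
combined	MG	B	yhdP	2440-2443/3801	DEL	Coding (2440-2443/3801 nt) Δ2 bp	Transporter	1
combined	MG	B	yhdP	647/3801	INS	Coding (647/3801 nt) (TGGAGCC)1→2	Transporter	4
combined	MG	B	yhdP	200-201/3801	MOB	Coding (200-201/3801 nt) IS5 (-) +4 bp	Transporter	1
combined	DH1	B	yhdP	3102-3110/3801	MOB	Coding (3102-3110/3801 nt) IS element(+) +9 bp	Transporter	1
combined	DH1	B	yhdP	2887-2890/3801	DEL	Coding (2887-2890/3801 nt) Δ4 bp	Transporter	1
MG1655	MG	B	rpoC	359	SNP	P359L (CCA→CTA)	RNA synthesis	4
MG1655	MG	B	rpoC	773	SNP	F773Y (TTC→TAC)	RNA synthesis	6
MG1655	MG	B	rpoC	1075	SNP	R1075S (CGT→AGT)	RNA synthesis	1
MG1655	MG	B	cspC	33-41/210	MOB	Coding (33-41/210 nt) IS1 (-) +9 bp	Stress protein	1
MG1655	MG	E	cspC	37	SNP	Q37* (CAG→TAG)	Stress protein	1
MG1655	MG	B	rpsG	460/540	DEL	Coding (460/540 nt) Δ1 bp	Subunit of ribosome	1
MG1655	MG	B	rpsG	157	SNP	L157* (TTA→TGA)	Subunit of ribosome	2
MG1655	MG	E	rph	667/669	INS	Pseudogene (667/669 nt) +C	Nucleotide biosynthesis	2
MG1655	MG	B	pyrE/rph	span	DEL	Δ82 bp	Nucleotide biosynthesis	5
DH1	DH1	B	rho	61	SNP	G61E (GGA→GAA)	Transcription termination factor	2
DH1	DH1	E	rho	80	SNP	Y80H (TAC→CAC)	Transcription termination factor	5
DH1	DH1	B	rho	80	SNP	Y80C (TAC→TGC)	Transcription termination factor	2
DH1	DH1	E	rho	406	SNP	T406P (ACC→CCC)	Transcription termination factor	4
DH1	DH1	E	fhuA	337-479/2244	DEL	Coding (337-479/2244 nt) Δ143 bp	Transport of ferrichrome	1
DH1	DH1	E	fhuA	1442/2244	INS	Coding (1442/2244 nt) (GTCATAACGACCGCCTAGGG)1→2	Transport of ferrichrome	1
DH1	DH1	B	fhuA	2107/2244	DEL	Coding (2107/2244 nt) Δ1 bp	Transport of ferrichrome	2
DH1	DH1	E	fhuA	2129/2244	DEL	Coding (2129/2244 nt) Δ1 bp	Transport of ferrichrome	4
DH1	DH1	E	rcdA	55	SNP	L55S (TTG→TCG)	Transcription regulator	1
DH1	DH1	E	rcdA	338-341/537	MOB	Coding (338-341/537 nt) IS element(+) +4 bp	Transcription regulator	1
DH1	DH1	B	purB	404	SNP	K404T (AAG→ACG)	Nucleotide biosynthesis	2
DH1	DH1	E	purB	21	SNP	S21N (AGC→AAC)	Nucleotide biosynthesis	1
DH1	DH1	E	gadE	273-281/528	MOB	Coding (273-281/528 nt) IS element(-) +9 bp	Transcriptional activator	2
DH1	DH1	E	gadE	273-281/528	MOB	Coding (273-281/528 nt) IS element(+) +9 bp	Transcriptional activator	1
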