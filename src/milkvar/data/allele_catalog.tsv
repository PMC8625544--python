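#gene	allele_name	chrom	pos	ref	alt	required_allele	status	id
CSN1S1	B	6	85427427	A	G	A	reference	rs43703010
CSN1S1	C	6	85427427	A	G	G	known	rs43703010
CSN2	A1	6	85451298	A	C	A	reference	rs43703011
CSN2	A2	6	85451298	A	C	C	known	rs43703011
CSN2	L	6	85450908	T	C	C	known	rs715383373
CSN1S2	A	6	85533780	C	T	C	reference	rs441966828
CSN1S2	B	6	85533780	C	T	T	known	rs441966828
CSN3	B	6	85656736	T	C	T	reference	rs43703015
CSN3	A	6	85656736	T	C	C	known	rs43703015
CSN3	A	6	85656772	C	A	A	known	rs43703016
CSN3	K	6	85656526	C	T	T	novel-in-paper	ss7626433428
LALBA	B	5	31184282	C	T	C	reference	rs714688595
LALBA	F	5	31184282	C	T	T	novel-in-paper	rs714688595
LALBA	A	5	31184283	G	A	A	known	rs722550244
LALBA	E	5	31184696	A	G	G	known	rs465119286
LGB	B	11	103259232	C	T	C	reference	rs109625649
LGB	B1	11	103259232	C	T	T	novel-in-paper	rs109625649
LGB	K	11	103257980	A	AA	AA	novel-in-paper	ss7626433430
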