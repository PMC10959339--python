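protein	mutation	second_base	location	structure	exposure	conservation_grade	effect	clinical	maf
NET	L284Q	U->A	ECL3	loop	Exposed (F)	9	damaging	-
NET	I230T	U->C	ECL2	loop	Exposed	4	? damaging	-
NET	I428T	U->C	TM8	α-helix	Buried	5	damaging	-
NET	I537T	U->C	TM11	α-helix	Exposed	4	benign	-
NET	I549T	U->C	ECL6	β-strand	Exposed	2	benign	-	0.003
NET	F609Y	U->A	Intracellular	3/10-helix	-	8	damaging	Benign
DAT	I291T	U->C	ECL3	α-helix	Exposed	1	benign	-
DAT	I490T	U->C	TM10	α-helix	Exposed	4	? damaging	-
DAT	I540T	U->C	TM11	α-helix	Exposed	4	benign	Uncertain (Parkinsonism)
DAT	F143Y	U->A	TM3	α-helix	Exposed	3	benign	-
SERT	L434Q	U->A	TM8	α-helix	Buried (S)	9	damaging	-
SERT	I123T	U->C	TM2	α-helix	Exposed	5	? damaging	-
SERT	I165T	U->C	TM3	α-helix	Buried	7	benign	-
SERT	I168T	U->C	TM3	α-helix	Buried	7	damaging	-
SERT	I218T	U->C	ECL2	loop	Exposed	1	benign	-
SERT	I266T	U->C	TM4	α-helix	Buried	7	? damaging	-
SERT	I270T	U->C	TM4	α-helix	Buried	7	damaging	-
SERT	I408T	U->C	ECL4	5-helix	Buried	8	damaging	-
SERT	I625T	U->C	Intracellular	C-coil	-	-	benign	-
VMAT1	L49Q	U->A	ECL1	α-helix	Buried	8	damaging	-
VMAT1	I136T	U->C	ECL1	α-helix	Buried	8	benign	-	0.728
VMAT1	I168T	U->C	TM3	α-helix	Exposed	5	damaging	-	0.0014
VMAT1	I202T	U->C	TM4	α-helix	Exposed	5	? damaging	Uncertain (Inborn)
VMAT1	I309T	U->C	TM7	α-helix	Buried	8	benign	-
VMAT1	I393T	U->C	ECL5	α-helix	Exposed	7	damaging	-
VMAT1	I403T	U->C	TM10	α-helix	Buried	8	? damaging	-
VMAT1	I490T	U->C	Intracellular	α-helix	-	7	damaging	-
VMAT2	L12Q	U->A	Intracellular	α-helix	-	5	damaging	-
VMAT2	I149T	U->C	TM2	α-helix	Buried	8	benign	-
VMAT2	I174T	U->C	TM3	α-helix	Exposed	4	benign	-
VMAT2	I223T	U->C	TM5	α-helix	Exposed	7	? damaging	-
VMAT2	I339T	U->C	TM8	α-helix	Exposed	6	benign	-
VMAT2	I366T	U->C	TM9	α-helix	Exposed	4	benign	-
VMAT2	I458T	U->C	TM12	α-helix	Exposed	4	benign	-
VMAT2	I459T	U->C	TM12	α-helix	Exposed	5	benign	Uncertain
VMAT2	I500T	U->C	Intracellular	C-coil	-	1	benign	-
VMAT2	I505T	U->C	Intracellular	C-coil	-	4	benign	Uncertain
VMAT2	F148Y	U->A	TM2	α-helix	Exposed	6	damaging	-
VAChT	L49Q	U->A	TM1	α-helix	Buried (S)	9	damaging	-
VAChT	L218Q	U->A	TM5	α-helix	Buried (S)	9	benign	-
VAChT	I56T	U->C	ECL1	α-helix	Buried (S)	9	damaging	-
VAChT	I373T	U->C	TM9	α-helix	Exposed	3	benign	-
VAChT	I394T	U->C	TM10	α-helix	Buried	8	damaging	-
VPAT	L258Q	U->A	ECL4	α-helix	-	8	damaging	-
VPAT	L294Q	U->A	ICL4	α-helix	-	4	damaging	-
VPAT	I240T	U->C	TM7	α-helix	-	5	benign	Uncertain (Inborn)
VPAT	F277Y	U->A	TM8	α-helix	-	8	damaging	-
NET	T99I	C->U	TM2	α-helix	Exposed	3	benign	Benign	0.0094
NET	T168I	C->U	ECL2	loop	Exposed	5	damaging	-
NET	T186I	C->U	ECL2	loop	Exposed	4	benign	-
NET	T353I	C->U	TM7	α-helix	Buried (S)	9	damaging	-
DAT	Q509L	A->U	ICL5	α-helix	Exposed	4	benign	-
DAT	T46I	C->U	TM9	N-coil	-	5	benign	-
DAT	T286I	C->U	ECL3	3/10-helix	Exposed (F)	8	? damaging	-
DAT	T566I	C->U	TM12	α-helix	Exposed	4	benign	-
SERT	T67I	C->U	Intracellular	N-coil	-	5	benign	-
SERT	T178I	C->U	TM3	α-helix	Buried	7	damaging	-
SERT	T221I	C->U	ECL2	loop	Exposed	3	benign	-
SERT	T421I	C->U	ECL4	α-helix	Exposed	6	damaging	-
SERT	T472I	C->U	TM9	α-helix	Exposed	2	benign	-
SERT	T480I	C->U	TM9	3/10-helix	Buried	6	damaging	-
SERT	Y134F	A->U	TM2	α-helix	Buried	6	damaging	-
SERT	Y570F	A->U	ECL6	loop	Buried	7	benign	-
VMAT1	T39I	C->U	TM1	3/10-helix	Buried	8	damaging	-
VMAT1	T47I	C->U	ECL1	α-helix	Exposed	7	? damaging	-
VMAT1	T322I	C->U	ECL4	α-helix	Buried	8	damaging	-
VMAT1	T353I	C->U	TM8	α-helix	Buried	8	damaging	-
VMAT1	T464I	C->U	TM12	α-helix	Buried	7	benign	-
VMAT1	T499I	C->U	Intracellular	C-coil	-	3	? damaging	-
VMAT2	Q280L	A->U	ICL3	loop	Exposed	3	benign	-
VMAT2	Q329L	A->U	TM8	3/10-helix	Exposed	7	benign	-
VMAT2	T68I	C->U	ECL1	loop	-	4	benign	Benign	0.0015
VMAT2	T97I	C->U	ECL1	loop	-	1	benign	-
VMAT2	T103I	C->U	ECL1	loop	-	3	benign	-
VMAT2	T140I	C->U	TM2	α-helix	Exposed	5	benign	Uncertain
VMAT2	T153I	C->U	ICL1	α-helix	Buried (S)	9	damaging	-
VMAT2	T322I	C->U	ECL4	α-helix	Exposed	6	? damaging	-
VMAT2	Y293F	A->U	TM7	α-helix	Exposed	7	damaging	-
VAChT	T81I	C->U	ECL1	loop	-	6	benign	-
VAChT	T97I	C->U	ECL1	loop	-	2	benign	-
VAChT	T311I	C->U	ECL4	α-helix	Buried	8	damaging	-
VAChT	Y236F	A->U	ECL3	α-helix	Exposed (F)	9	benign	-
VAChT	Y359F	A->U	TM9	α-helix	Buried	5	? damaging	Uncertain
VPAT	T114I	C->U	TM3	α-helix	-	8	benign	-
VPAT	T257I	C->U	ECL4	α-helix	-	9	benign	-
VPAT	T313I	C->U	TM9	α-helix	-	5	benign	Uncertain (Inborn)
VPAT	T372I	C->U	ICL5	α-helix	-	9	? damaging	-
VPAT	T444I	C->U	Intracellular	α-helix	-	6	? damaging	-
VPAT	T449I	C->U	Intracellular	α-helix	-	5	? damaging	-
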