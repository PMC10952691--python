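# Published Present/Absent trait calls for the two genomes.
ShortTraitName	Thiobius	ODIII6
ActP	Present	Absent
Cbb	Present	Present
Glg	Absent	Present
GlC	Present	Absent
LakP	Present	Absent
Lut	Present	Absent
Pha	Present	Absent
TcaC	Present	Present
Cph	Absent	Present
Hup	Absent	Present
AmtB	Present	Present
AsN	Present	Present
iUcy	Present	Present
Nrt	Present	Present
Urt	Present	Present
Ure	Present	Present
CytAA3	Present	Present
CytBA3	Absent	Present
Pet	Present	Present
CytBD	Absent	Present
CytCBB3	Present	Present
Hnp	Absent	Present
Pst	Present	Present
Pit	Absent	Present
PHK and PHX	Present	Present
AprSat	Present	Present
rDsr	Present	Present
Tst	Absent	Present
SulP	Absent	Present
CysZ	Present	Present
Hyd	Absent	Present
Psr	Absent	Present
Fcsd	Present	Present
Sqr	Present	Present
Soe	Present	Present
Sgp	Present	Present
Sor	Absent	Present
YeeE	Absent	Present
tSox	Present	Present
Cas	Present	Absent
T1SS	Absent	Present
T2SS	Present	Present
T5SS	Present	Present
T6SS	Present	Absent
Fla	Absent	Present
T4P	Present	Present
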