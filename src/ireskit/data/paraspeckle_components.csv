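name,alternative_name,class,itaf,presence_in_ms
ASXL1,MDS/BOPS,I,No,No
CELF6,,n/d,No,No
CIRBP,,IIIB,No,Yes
CPSF6,,IIIA,No,Yes
CPSF7,,II,No,Yes
DAZAP1,,IB,No,Yes
DLX3,,n/d,No,No
EWSR1,,,No,Yes
FAM113A,,II,No,No
FAM98A,,II,No,Yes
FIGN,,II,No,No
FUS,,IB,Yes,Yes
FUSPI1,SRSF10,II,No,Yes
hnRNPA1,,II,Yes,Yes
hnRNPA1L2,,n/d,No,No
hnRNPF,,n/d,No,Yes
hnRNPH1,,n/d,No,Yes
hnRNPH3,,IB,No,No
hnRNPK,,IA,Yes,Yes
hnRNPM,,n/d,Yes,Yes
hnRNPR,,II,Yes,No
hnRNPUL1,,II,No,Yes
MEX3C,,n/d,No,No
NUDT21,,IIIA,No,Yes
p54nrb,NONO,IA,Yes,Yes
PSPC1,,IIIB,No,Yes
RBM12,,II,No,No
RBM14,,IA,No,No
RBM3,,IIIB,No,Yes
RBM4B,,IIIB,No,No
RBM7,,IIIB,No,No
RBMX,,IIIB,No,Yes
RUNX3,,IIIB,No,No
SFPQ,PSF,IA,Yes,Yes
SS18L1,,n/d,No,No
SWI/SNF,,IB,No,No
TAF15,,,No,No
TDP-43,,II,No,No
UBAP2L,,IIIA,No,Yes
ZNF335,TARDBP,IIIB,No,Yes
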