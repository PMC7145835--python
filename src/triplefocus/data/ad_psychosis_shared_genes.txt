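# Gene symbols shared between the Alzheimer's disease and psychosis
# interactome seed lists of the published case study (90 symbols).
SEMA3A
TUSC3
RPN2
AMBRA1
BECN1
CACNA1C
SGK1
ADAM10
GRIN2A
FYN
ANK3
TBXAS1
EFNA5
POLN
CHRNA3
NOTCH4
GRIA1
NTRK3
IQGAP2
RELN
NOS1
GPC6
TCF7L2
TCF4
MGLL
DRD3
CHRNA2
PAK2
CTNNA2
COL25A1
COL12A1
AGER
KIF26B
PPP2R2B
TEK
KALRN
PRKG1
KSR2
COLGALT2
MEIS1
SHISA9
ZKSCAN4
PTPRG
NKAPL
CTNNA3
PDE4B
HFE
MSR1
CSMD1
COMT
APBA1
IMMP2L
ELAVL4
LRRTM4
CDH13
ZNF804A
PBRM1
LRRN2
TEP1
STXBP5L
FHIT
SYNGAP1
ZSCAN31
TENM4
ABCB1
PLCL1
RBFOX1
FSTL5
SORCS3
NKAIN2
GLIS3
NXN
MAGI2
MEGF10
MPP6
TSPAN18
FRMD4B
MTHFD1L
TMTC1
LIN28B
UXS1
BICC1
ATXN7L1
EYS
GRAMD1B
TSPAN2
ENOX1
TMEM132D
CR1
PCNX
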