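# Known candidate genes for depigmentation / albinism phenotypes in cattle
# and other mammals (gene-level evidence for the classifier).
DCT
EDNRA
EDN3
KIT
KITLG
LRMDA
MFSD12
MITF
OCA2
OCA5
PAX3
PMEL
SLC24A5
SLC45A2
SOX10
TRPM1
TYR
TYRP1
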