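ACTB
GAPDH
B2M
TUBB
TBP
PPIA
HPRT1
RPLP0
GUSB
PGK1
YWHAZ
SDHA
UBC
EEF1A1
POLR2A
TFRC
HMBS
PSMB4
RAB7A
CHMP2A
EMC7
GPI
VCP
VPS29
SNRPD3
REEP5
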