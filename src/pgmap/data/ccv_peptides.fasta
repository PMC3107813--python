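>Proteinase-1 frame=+1
NLDLLDNSTG
>Proteinase-2 frame=+1
LMPCSMSS
>Proteinase-3 frame=-1
PSPVSSHPLAASVSGPC
>Proteinase-4 frame=+3
MRELVSM
>Proteinase-5 frame=-1
RNDIAESSCLVA
>Proteinase-6 frame=+3
ISRDSIPILF
>Proteinase-7 frame=-2
QAVVPMNTF
>Proteinase-8 frame=+3
QLGDGPLGGGHVDHIPF
>Proteinase-9 frame=+2
ARDLPRRF
>Proteinase-10 frame=-1
EVVILQ
>Trypsine-1 frame=+3
IPFVSGLMNAQIILFSGPCMIGRNAAVSCK
>Trypsine-2 frame=+3
ARTVFLNVRPGWSR
>Trypsine-3 frame=+3
EGQAQRTCAYPSAGLLQASQGR
>Trypsine-4 frame=-1
PCSRTSGSGACSGR
>Trypsine-5 frame=-2
NRTRVYTMPGWR
>Trypsine-6 frame=-1
LKSPPGLRK
>Trypsine-7 frame=+3
VARGEDATCPNDKGSEPR
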