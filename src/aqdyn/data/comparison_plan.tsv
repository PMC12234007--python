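group_a	group_b	variable
WT	Tg	iop
Tg	sham_short	iop
Tg	sham_mid	iop
Tg	sham_long	iop
Tg	hAMSC_short	iop
Tg	hAMSC_mid	iop
Tg	hAMSC_long	iop
Tg	iPSC-TM_short	iop
Tg	iPSC-TM_mid	iop
sham_short	hAMSC_short	iop
sham_short	iPSC-TM_short	iop
hAMSC_short	hAMSC_mid	iop
hAMSC_short	hAMSC_long	iop
hAMSC_short	iPSC-TM_short	iop
sham_mid	hAMSC_mid	iop
sham_mid	iPSC-TM_mid	iop
hAMSC_mid	hAMSC_long	iop
hAMSC_mid	iPSC-TM_mid	iop
sham_long	hAMSC_long	iop
iPSC-TM_short	iPSC-TM_mid	iop
WT	Tg	facility
Tg	sham_short	facility
Tg	sham_mid	facility
Tg	sham_long	facility
Tg	hAMSC_short	facility
Tg	hAMSC_mid	facility
Tg	hAMSC_long	facility
Tg	iPSC-TM_short	facility
Tg	iPSC-TM_mid	facility
sham_short	hAMSC_short	facility
sham_short	iPSC-TM_short	facility
hAMSC_short	hAMSC_mid	facility
hAMSC_short	hAMSC_long	facility
hAMSC_short	iPSC-TM_short	facility
sham_mid	hAMSC_mid	facility
sham_mid	iPSC-TM_mid	facility
hAMSC_mid	hAMSC_long	facility
hAMSC_mid	iPSC-TM_mid	facility
sham_long	hAMSC_long	facility
iPSC-TM_short	iPSC-TM_mid	facility
WT	Tg	cellularity
Tg	sham_short	cellularity
Tg	sham_mid	cellularity
Tg	sham_long	cellularity
Tg	hAMSC_short	cellularity
Tg	hAMSC_mid	cellularity
Tg	hAMSC_long	cellularity
Tg	iPSC-TM_short	cellularity
Tg	iPSC-TM_mid	cellularity
sham_short	hAMSC_short	cellularity
sham_short	iPSC-TM_short	cellularity
hAMSC_short	hAMSC_mid	cellularity
hAMSC_short	hAMSC_long	cellularity
hAMSC_short	iPSC-TM_short	cellularity
sham_mid	hAMSC_mid	cellularity
sham_mid	iPSC-TM_mid	cellularity
hAMSC_mid	hAMSC_long	cellularity
hAMSC_mid	iPSC-TM_mid	cellularity
sham_long	hAMSC_long	cellularity
iPSC-TM_short	iPSC-TM_mid	cellularity
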