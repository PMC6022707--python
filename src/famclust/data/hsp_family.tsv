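gene_id	subfamily
HSP90AA1	HSPC
HSP90AB1	HSPC
HSP90B1	HSPC
TRAP1	HSPC
TCP1	CHAP
CCT2	CHAP
CCT3	CHAP
CCT4	CHAP
CCT5	CHAP
CCT6A	CHAP
CCT6B	CHAP
CCT7	CHAP
CCT8	CHAP
CCT8L2	CHAP
MKKS	CHAP
BBS10	CHAP
BBS12	CHAP
HSPD1	CHAP
HSPE1	CHAP
HSPA1A	HSP70
HSPA1B	HSP70
HSPA1L	HSP70
HSPA2	HSP70
HSPA4	HSP70
HSPA4L	HSP70
HSPA5	HSP70
HSPA6	HSP70
HSPA7	HSP70
HSPA8	HSP70
HSPA9	HSP70
HSPA12A	HSP70
HSPA12B	HSP70
HSPA13	HSP70
HSPA14	HSP70
HSPH1	HSP70
HYOU1	HSP70
HSPB1	HSPB
HSPB2	HSPB
HSPB3	HSPB
CRYAA	HSPB
CRYAB	HSPB
HSPB6	HSPB
HSPB7	HSPB
HSPB8	HSPB
HSPB9	HSPB
ODF1	HSPB
HSPB11	HSPB
DNAJA1	DNAJ
DNAJA2	DNAJ
DNAJA3	DNAJ
DNAJA4	DNAJ
DNAJB1	DNAJ
DNAJB2	DNAJ
DNAJB3	DNAJ
DNAJB4	DNAJ
DNAJB5	DNAJ
DNAJB6	DNAJ
DNAJB7	DNAJ
DNAJB8	DNAJ
DNAJB9	DNAJ
DNAJB11	DNAJ
DNAJB12	DNAJ
DNAJB13	DNAJ
DNAJB14	DNAJ
DNAJC1	DNAJ
DNAJC2	DNAJ
DNAJC3	DNAJ
DNAJC4	DNAJ
DNAJC5	DNAJ
DNAJC5B	DNAJ
DNAJC5G	DNAJ
DNAJC6	DNAJ
DNAJC7	DNAJ
DNAJC8	DNAJ
DNAJC9	DNAJ
DNAJC10	DNAJ
DNAJC11	DNAJ
DNAJC12	DNAJ
DNAJC13	DNAJ
DNAJC14	DNAJ
DNAJC15	DNAJ
DNAJC16	DNAJ
DNAJC17	DNAJ
DNAJC18	DNAJ
DNAJC19	DNAJ
DNAJC21	DNAJ
DNAJC22	DNAJ
DNAJC24	DNAJ
DNAJC25	DNAJ
DNAJC27	DNAJ
DNAJC28	DNAJ
DNAJC30	DNAJ
SACS	DNAJ
SEC63	DNAJ
HSCB	DNAJ
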