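no	reaction	frequency	target
1	RKIP + Raf1 -> RKIP|Raf1	405	Yes
2	MEKPP + RKIP -> MEKPP|RKIP	407	No
3	RKIPP|Raf1 -> RKIPPP + Raf1	415	No
4	ERK + MEKPP -> ERK|MEKPP	429	Yes
5	ERK|MEKPP -> ERKP + MEKPP	429	No
6	MEKPP|RKIPP -> RKIPPP + MEKPP	433	No
7	RKIP + RP -> RKIP|RP	469	No
8	MEKPP|RKIP -> RKIPP + MEKPP	471	No
9	ERKPP|MEKPP -> ERKPP + MEKPP	483	No
10	MEKPP + RKIPP -> MEKPP|RKIPP	639	No
11	ERKPP|MEKPP -> ERKPPP + MEKPP	761	No
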