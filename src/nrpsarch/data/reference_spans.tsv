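reference_id	motif_id	start	end
refC	C1	21	30
refC	C2	61	69
refC	C3	110	119
refC	C4	170	176
refC	C5	242	252
refC	C6	298	304
refC	C7	365	372
refA	Aa1	6	11
refA	A1	21	26
refA	A2	55	66
refA	A3	137	152
refA	A4	178	181
refA	A5	258	264
refA	G	282	288
refA	A6	308	322
refA	A7	351	356
refA	A8	377	396
refA	A9	432	438
refA	A10	457	462
refT	Ta1	6	16
refT	T1	24	29
refE	E1	13	18
refE	E2	44	52
refE	E3	83	90
refE	E4	131	136
refE	E5	172	183
refE	E6	224	231
refE	E7	257	262
refTE	TE1	56	60
refACP	ACP1	36	41
refC_CT	C1	21	30
refC_CT	C2	61	69
refC_CT	C3	110	119
refC_CT	C4	170	176
refC_CT	C5	242	252
refC_CT	C6	298	304
refC_CT	C7	365	372
refC_CT-DCL	C1	21	30
refC_CT-DCL	C2	61	69
refC_CT-DCL	C3	110	119
refC_CT-DCL	C4	170	176
refC_CT-DCL	C5	242	252
refC_CT-DCL	C6	298	304
refC_CT-DCL	C7	365	372
refC_CT-A	C1	21	30
refC_CT-A	C2	61	69
refC_CT-A	C3	110	119
refC_CT-A	C4	170	176
refC_CT-A	C5	242	252
refC_CT-A	C6	298	304
refC_CT-A	C7	365	372
refC_LCL-A	C1	21	30
refC_LCL-A	C2	61	69
refC_LCL-A	C3	110	119
refC_LCL-A	C4	170	176
refC_LCL-A	C5	242	252
refC_LCL-A	C6	298	304
refC_LCL-A	C7	365	372
refC_FUM14	C1	21	30
refC_FUM14	C2	61	69
refC_FUM14	C3	110	119
refC_FUM14	C4	170	176
refC_FUM14	C5	242	252
refC_FUM14	C6	298	304
refC_FUM14	C7	365	372
refC_SgcC5	C1	21	30
refC_SgcC5	C2	61	69
refC_SgcC5	C3	110	119
refC_SgcC5	C4	170	176
refC_SgcC5	C5	242	252
refC_SgcC5	C6	298	304
refC_SgcC5	C7	365	372
refC_Cglyc	C1	21	30
refC_Cglyc	C2	61	69
refC_Cglyc	C3	110	119
refC_Cglyc	C4	170	176
refC_Cglyc	C5	242	252
refC_Cglyc	C6	298	304
refC_Cglyc	C7	365	372
refC_Dual	C1	21	30
refC_Dual	C2	61	69
refC_Dual	C3	110	119
refC_Dual	C4	170	176
refC_Dual	C5	242	252
refC_Dual	C6	298	304
refC_Dual	C7	365	372
refC_Starter	C1	21	30
refC_Starter	C2	61	69
refC_Starter	C3	110	119
refC_Starter	C4	170	176
refC_Starter	C5	242	252
refC_Starter	C6	298	304
refC_Starter	C7	365	372
refC_Cyc	C1	21	30
refC_Cyc	C2	61	69
refC_Cyc	C3	110	119
refC_Cyc	C4	170	176
refC_Cyc	C5	242	252
refC_Cyc	C6	298	304
refC_Cyc	C7	365	372
refC_X	C1	21	30
refC_X	C2	61	69
refC_X	C3	110	119
refC_X	C4	170	176
refC_X	C5	242	252
refC_X	C6	298	304
refC_X	C7	365	372
refC_I	C1	21	30
refC_I	C2	61	69
refC_I	C3	110	119
refC_I	C4	170	176
refC_I	C5	242	252
refC_I	C6	298	304
refC_I	C7	365	372
refC_PS	C1	21	30
refC_PS	C2	61	69
refC_PS	C3	110	119
refC_PS	C4	170	176
refC_PS	C5	242	252
refC_PS	C6	298	304
refC_PS	C7	365	372
refC_bL	C1	21	30
refC_bL	C2	61	69
refC_bL	C3	110	119
refC_bL	C4	170	176
refC_bL	C5	242	252
refC_bL	C6	298	304
refC_bL	C7	365	372
refC_modAA	C1	21	30
refC_modAA	C2	61	69
refC_modAA	C3	110	119
refC_modAA	C4	170	176
refC_modAA	C5	242	252
refC_modAA	C6	298	304
refC_modAA	C7	365	372
refC_Hybrid	C1	21	30
refC_Hybrid	C2	61	69
refC_Hybrid	C3	110	119
refC_Hybrid	C4	170	176
refC_Hybrid	C5	242	252
refC_Hybrid	C6	298	304
refC_Hybrid	C7	365	372
refC_LCL	C1	21	30
refC_LCL	C2	61	69
refC_LCL	C3	110	119
refC_LCL	C4	170	176
refC_LCL	C5	242	252
refC_LCL	C6	298	304
refC_LCL	C7	365	372
refC_DCL	C1	21	30
refC_DCL	C2	61	69
refC_DCL	C3	110	119
refC_DCL	C4	170	176
refC_DCL	C5	242	252
refC_DCL	C6	298	304
refC_DCL	C7	365	372
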