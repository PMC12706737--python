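peak_id,fraction
PCB1,0.00311110944
PCB2,0.00077777986
PCB3,0.00311110944
PCB4,0.02916666475
PCB5,0.007291668687
PCB6,0.02916666475
PCB7,0.007291668687
PCB8,0.02916666475
PCB9,0.007291668687
PCB10,0.007291668687
PCB11,0.007291668687
PCB12,0.007291668687
PCB13,0.007291668687
PCB14,0.007291668687
PCB15,0.02916666475
PCB16,0.03639999345
PCB17,0.03639999345
PCB18+30,0.04549999181
PCB19,0.03639999345
PCB20+28,0.04549999181
PCB21,0.009099998362
PCB22,0.03639999345
PCB23,0.009099998362
PCB24,0.009099998362
PCB25,0.03639999345
PCB26,0.03639999345
PCB27,0.009099998362
PCB29,0.009099998362
PCB31,0.03639999345
PCB32,0.03639999345
PCB33,0.03639999345
PCB34,0.009099998362
PCB35,0.009099998362
PCB36,0.009099998362
PCB37,0.03639999345
PCB38,0.009099998362
PCB39,0.009099998362
PCB40+41+71,0.01977777644
PCB42,0.01318518763
PCB43,0.003296299407
PCB44+47+65,0.02966666466
PCB45+51,0.01648147703
PCB46,0.003296299407
PCB48,0.01318518763
PCB49,0.01318518763
PCB50+53,0.006592588813
PCB52,0.01318518763
PCB54,0.003296299407
PCB55,0.003296299407
PCB56,0.01318518763
PCB57,0.003296299407
PCB58,0.003296299407
PCB59,0.003296299407
PCB60,0.003296299407
PCB61+70+74+76,0.03296295407
PCB62,0.003296299407
PCB63,0.003296299407
PCB64,0.01318518763
PCB66,0.01318518763
PCB67,0.003296299407
PCB68,0.003296299407
PCB69,0.003296299407
PCB72,0.003296299407
PCB73,0.003296299407
PCB75,0.003296299407
PCB77,0.003296299407
PCB78,0.003296299407
PCB79,0.003296299407
PCB80,0.003296299407
PCB81,0.003296299407
PCB82,6.578998816e-05
PCB83+99,0.0003289499408
PCB84,0.0002631599526
PCB85,0.0002631599526
PCB86+87+97+109+119+125,0.0007894698579
PCB88,6.578998816e-05
PCB89,6.578998816e-05
PCB90+101+113,0.0003947399289
PCB91,0.0002631599526
PCB92,6.578998816e-05
PCB93+95+98+100+102,0.0005263199053
PCB94,6.578998816e-05
PCB96,6.578998816e-05
PCB103,6.578998816e-05
PCB104,6.578998816e-05
PCB105,6.578998816e-05
PCB106,6.578998816e-05
PCB107+124,0.0001315799763
PCB108,6.578998816e-05
PCB110+115,0.0003289499408
PCB111,6.578998816e-05
PCB112,6.578998816e-05
PCB114,6.578998816e-05
PCB116,6.578998816e-05
PCB117,6.578998816e-05
PCB118,0.0002631599526
PCB120,6.578998816e-05
PCB121,6.578998816e-05
PCB122,6.578998816e-05
PCB123,6.578998816e-05
PCB126,6.578998816e-05
PCB127,6.578998816e-05
PCB128+166,0
PCB129+138+163,0
PCB130,0
PCB131,0
PCB132,0
PCB133,0
PCB134,0
PCB135+151,0
PCB136,0
PCB137,0
PCB139,0
PCB140,0
PCB141,0
PCB142,0
PCB143,0
PCB144,0
PCB145,0
PCB146,0
PCB147+149,0
PCB148,0
PCB150,0
PCB152,0
PCB153+168,0
PCB154,0
PCB155,0
PCB156+157,0
PCB158,0
PCB159,0
PCB160,0
PCB161,0
PCB162,0
PCB164,0
PCB165,0
PCB167,0
PCB169,0
PCB170,0
PCB171,0
PCB172,0
PCB173,0
PCB174,0
PCB175,0
PCB176,0
PCB177,0
PCB178,0
PCB179,0
PCB180+193,0
PCB181,0
PCB182,0
PCB183+185,0
PCB184,0
PCB186,0
PCB187,0
PCB188,0
PCB189,0
PCB190,0
PCB191,0
PCB192,0
PCB194,0
PCB195,0
PCB196,0
PCB197+200,0
PCB198+199,0
PCB201,0
PCB202,0
PCB203,0
PCB204,0
PCB205,0
PCB206,0
PCB207,0
PCB208,0
PCB209,0
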