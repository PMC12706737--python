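peak_id,fraction
PCB1,0.004444440978
PCB2,0.001111110244
PCB3,0.004444440978
PCB4,0.02250000495
PCB5,0.005625001238
PCB6,0.02250000495
PCB7,0.005625001238
PCB8,0.02250000495
PCB9,0.005625001238
PCB10,0.005625001238
PCB11,0.005625001238
PCB12,0.005625001238
PCB13,0.005625001238
PCB14,0.005625001238
PCB15,0.02250000495
PCB16,0.03040000669
PCB17,0.03040000669
PCB18+30,0.03800000836
PCB19,0.03040000669
PCB20+28,0.03800000836
PCB21,0.007600001672
PCB22,0.03040000669
PCB23,0.007600001672
PCB24,0.007600001672
PCB25,0.03040000669
PCB26,0.03040000669
PCB27,0.007600001672
PCB29,0.007600001672
PCB31,0.03040000669
PCB32,0.03040000669
PCB33,0.03040000669
PCB34,0.007600001672
PCB35,0.007600001672
PCB36,0.007600001672
PCB37,0.03040000669
PCB38,0.007600001672
PCB39,0.007600001672
PCB40+41+71,0.02229630491
PCB42,0.01486420327
PCB43,0.003716050818
PCB44+47+65,0.03344444736
PCB45+51,0.01858025409
PCB46,0.003716050818
PCB48,0.01486420327
PCB49,0.01486420327
PCB50+53,0.007432101635
PCB52,0.01486420327
PCB54,0.003716050818
PCB55,0.003716050818
PCB56,0.01486420327
PCB57,0.003716050818
PCB58,0.003716050818
PCB59,0.003716050818
PCB60,0.003716050818
PCB61+70+74+76,0.03716049818
PCB62,0.003716050818
PCB63,0.003716050818
PCB64,0.01486420327
PCB66,0.01486420327
PCB67,0.003716050818
PCB68,0.003716050818
PCB69,0.003716050818
PCB72,0.003716050818
PCB73,0.003716050818
PCB75,0.003716050818
PCB77,0.003716050818
PCB78,0.003716050818
PCB79,0.003716050818
PCB80,0.003716050818
PCB81,0.003716050818
PCB82,0.001105260243
PCB83+99,0.005526321216
PCB84,0.004421050973
PCB85,0.004421050973
PCB86+87+97+109+119+125,0.01326316292
PCB88,0.001105260243
PCB89,0.001105260243
PCB90+101+113,0.006631581459
PCB91,0.004421050973
PCB92,0.001105260243
PCB93+95+98+100+102,0.008842111945
PCB94,0.001105260243
PCB96,0.001105260243
PCB103,0.001105260243
PCB104,0.001105260243
PCB105,0.001105260243
PCB106,0.001105260243
PCB107+124,0.002210530486
PCB108,0.001105260243
PCB110+115,0.005526321216
PCB111,0.001105260243
PCB112,0.001105260243
PCB114,0.001105260243
PCB116,0.001105260243
PCB117,0.001105260243
PCB118,0.004421050973
PCB120,0.001105260243
PCB121,0.001105260243
PCB122,0.001105260243
PCB123,0.001105260243
PCB126,0.001105260243
PCB127,0.001105260243
PCB128+166,0.0005714301257
PCB129+138+163,0.0008571401886
PCB130,0.0002857100629
PCB131,0.0002857100629
PCB132,0.0002857100629
PCB133,0.0002857100629
PCB134,0.0002857100629
PCB135+151,0.0005714301257
PCB136,0.0002857100629
PCB137,0.0002857100629
PCB139,0.0002857100629
PCB140,0.0002857100629
PCB141,0.0002857100629
PCB142,0.0002857100629
PCB143,0.0002857100629
PCB144,0.0002857100629
PCB145,0.0002857100629
PCB146,0.0002857100629
PCB147+149,0.0005714301257
PCB148,0.0002857100629
PCB150,0.0002857100629
PCB152,0.0002857100629
PCB153+168,0.0005714301257
PCB154,0.0002857100629
PCB155,0.0002857100629
PCB156+157,0.0005714301257
PCB158,0.0002857100629
PCB159,0.0002857100629
PCB160,0.0002857100629
PCB161,0.0002857100629
PCB162,0.0002857100629
PCB164,0.0002857100629
PCB165,0.0002857100629
PCB167,0.0002857100629
PCB169,0.0002857100629
PCB170,8.333001833e-05
PCB171,8.333001833e-05
PCB172,8.333001833e-05
PCB173,8.333001833e-05
PCB174,8.333001833e-05
PCB175,8.333001833e-05
PCB176,8.333001833e-05
PCB177,8.333001833e-05
PCB178,8.333001833e-05
PCB179,8.333001833e-05
PCB180+193,0.0001666700367
PCB181,8.333001833e-05
PCB182,8.333001833e-05
PCB183+185,0.0001666700367
PCB184,8.333001833e-05
PCB186,8.333001833e-05
PCB187,8.333001833e-05
PCB188,8.333001833e-05
PCB189,8.333001833e-05
PCB190,8.333001833e-05
PCB191,8.333001833e-05
PCB192,8.333001833e-05
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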