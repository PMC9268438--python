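no,rt_min,name,formula,mass_ion_mz,ion_type,error_ppm,fragment_ions,reference,notes
1,1.07,Quinquenoside L9 or its isomer,C42H74O15,863.4940,[M+HCOO]-,-6.80,,B22,
2,1.07,Ginsenoside Re2 or its isomer,C48H82O19,1007.5422,[M+HCOO]-,0.05,,B16,
3,4.23,Ginsenoside Re2 or its isomer,C48H82O19,1007.5422,[M+HCOO]-,0.05,961.5401;799.4824;781.4713,B16,
4,4.74,(B4-b)-glc-xyl,C41H70O14,831.4737,[M+HCOO]-,-0.01,785.4677;653.4273;491.3746,B22,
5,5.18,Notoginsenoside R8 or its isomer,C36H62O10,699.4315,[M+HCOO]-,0.13,,B22,
6,5.73,Ginsenoside Re4 or its isomer,C47H80O18,977.5353,[M+HCOO]-,3.79,977.5353;931.5271;637.4358;457.3784,B23,ion type printed [M-H]- but m/z matches the formate adduct (cf. rows 9 and 12 of the same compound); transcribed as [M+HCOO]-
7,6.13,Ginsenoside Re2 or its isomer,C48H82O19,1007.5438,[M+HCOO]-,1.71,961.5419;799.4876;637.4357;475.3806,B16,
8,6.97,Notoginsenoside R1,C47H80O18,931.5260,[M-H]-,-1.28,931.5220;799.4836;638.4292;475.3696,B23,
9,7.37,Ginsenoside Re4,C47H80O18,977.5330,[M+HCOO]-,1.43,931.5302;637.4335;475.3784,B23,
10,8.11,Ginsenoside Rc or its isomer,C53H90O22,1077.5829,[M-H]-,-2.06,945.5438;719.3460;433.5658,B21,
11,8.40,Ginsenoside Re3,C48H82O19,961.5365,[M-H]-,-1.33,799.4859;637.4300,B23,
12,9.37,Ginsenoside Re4 or its isomer,C47H80O18,977.5308,[M+HCOO]-,-0.81,931.5203;637.4289;475.3736,B23,
13,10.83,Ginsenoside Rg1,C42H72O14,845.4912,[M+HCOO]-,2.27,799.4852;637.4337;619.4215;475.3802,B23,
14,11.70,Ginsenoside Re,C48H82O18,945.5426,[M-H]-,-0.21,799.4880;783.4926;637.4346;475.3818,B23,
15,11.70,Ginsenoside Re2 or its isomer,C48H82O19,961.5377,[M-H]-,-0.11,,B16,
16,12.95,Vinaginsenoside R13 or its isomer,C48H84O20,979.5454,[M-H]-,-2.94,,B22,
17,14.51,Vinaginsenoside R13 or its isomer,C48H84O20,979.5470,[M-H]-,-1.38,,B22,formula printed C48H84O21 but m/z and printed ppm error match C48H84O20 (cf. row 16 of the same compound); transcribed as C48H84O20
18,14.59,AcO-ginsenoside Re or its isomer,C50H84O19,987.5527,[M-H]-,-0.74,945.5519;927.5335;783.4923;765.5022;637.4373,B23,
19,14.71,AcO-ginsenoside Rf or its isomer,C44H74O15,841.4946,[M-H]-,-1.12,637.4308;619.4205;475.3759,B22,
20,15.43,Notoginsenoside G or its isomer,C48H80O19,1005.5209,[M+HCOO]-,-5.57,,B22,
21,15.71,Notoginsenoside R2,C41H70O13,815.4791,[M+HCOO]-,0.31,,B23,
22,16.29,Ginsenoside F5,C41H70O13,815.4789,[M+HCOO]-,0.16,,B22,
23,16.19,Notoginsenoside C or its isomer,C54H92O25,1139.5831,[M-H]-,-2.08,961.5606;785.8238;584.0663,B22,
24,17.06,Notoginsenoside M or its isomer,C42H70O14,843.4734,[M+HCOO]-,-0.40,,B22,
25,16.92,Ginsenoside Re2 or its isomer,C48H82O19,1007.5416,[M+HCOO]-,-0.51,961.5419;799.4876;637.4357;475.3806,B16,
26,17.39,Ginsenoside Re2 or its isomer,C48H82O19,1007.5419,[M+HCOO]-,-0.20,961.5314;799.4734,B16,
27,18.65,Ginsenoside Rf,C42H72O14,799.4858,[M-H]-,1.14,637.4327;475.3796,B21,
28,18.90,Ginsenoside Re6 or its isomer,C46H76O15,913.5158,[M+HCOO]-,0.27,830.6457;765.8931;620.4240;475.3751,B22,
29,19.24,Notoginsenoside D or its isomer,C64H108O31,1371.6754,[M-H]-,-3.49,1273.1482;1031.7337;875.6615;597.4910;415.6329,B22,
30,19.62,Notoginsenoside D or its isomer,C64H108O31,1371.6777,[M-H]-,-1.84,,B22,
31,19.88,AcO-ginsenoside Rg1,C44H74O15,841.4953,[M-H]-,-0.26,799.4865;679.4467;637.4326;619.4224;571.3972;475.3799,B23,
32,20.00,Notoginsenoside R4 or its isomer,C59H100O27,1239.6365,[M-H]-,-1.15,1107.5904;1077.5822;946.5432;945.5391;783.4854;621.4298;459.3820,B23,
33,20.53,Yesanchinoside J or its isomer,C61H102O28,1281.6480,[M-H]-,-0.37,,B22,
34,20.98,20(R)-Ginsenoside Rh1,C36H62O9,683.4372,[M+HCOO]-,1.08,475.3815,B24,
35,20.90,Quinquenoside V,C60H102O28,1269.6463,[M-H]-,-1.76,1107.6007,B22,
36,21.20,20(R)-Ginsenoside Rg2,C42H72O13,829.4967,[M+HCOO]-,2.74,783.4923;637.4372;619.4248;475.3808,B24,
37,21.33,Ginsenoside Rg5 or its isomer,C42H70O12,811.4842,[M+HCOO]-,0.54,,B22,
38,21.36,Notoginsenoside D or its isomer,C64H108O31,1371.6762,[M-H]-,-2.95,1145.2550;838.4987;652.4940;438.2765,B22,
39,21.41,Quinquenoside L1 or its isomer,C48H80O18,989.5313,[M+HCOO]-,-0.29,,B22,
40,21.80,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6252,[M-H]-,-1.83,1077.5829;945.5368;783.4866;621.7380,B23,
41,21.96,Notoginsenoside R4 or its isomer,C59H100O27,1239.6356,[M-H]-,-1.85,1077.5843;916.9001;621.4288,B23,formula printed C_59_H_100_O_2_7; transcribed as C59H100O27 (matches rows 32 and 47 of the same compound)
42,22.08,Quinquenoside I or its isomer,C52H86O19,1059.5727,[M+HCOO]-,-0.63,,B22,
43,22.11,Ginsenoside Ro or its isomer,C48H76O19,955.4896,[M-H]-,-1.29,,B23,
44,22.35,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6274,[M-H]-,0.03,1077.5874;945.5440;783.4925;621.4390,B23,
45,22.55,Ginsenoside F1 or its isomer,C36H62O9,683.4380,[M+HCOO]-,2.25,,B22,
46,22.70,Ginsenoside Rb1,C54H92O23,1153.6013,[M+HCOO]-,1.00,1107.5980;945.5438;783.4904;621.4370;323.0986,B21,
47,22.78,Notoginsenoside R4 or its isomer,C59H100O27,1239.6366,[M-H]-,-1.09,1209.6298;1077.5874;945.5440;783.4928;621.4390,B23,
48,22.98,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6188,[M-H]-,-7.10,1077.5826;945.5420,B23,
49,23.58,Ginsenoside Ro,C48H76O19,955.4924,[M-H]-,1.63,793.4392;569.3860;455.3534,B23,
50,24.01,Ginsenoside Rc,C53H90O22,1123.5915,[M+HCOO]-,1.77,1077.5879;945.5412;915.5334,B21,
51,24.46,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6282,[M-H]-,0.68,1077.5846;945.5437;915.5327;783.4863,B23,
52,25.04,Ginsenoside F1 or its isomer,C36H62O9,683.4371,[M+HCOO]-,0.94,,B22,
53,25.04,AcO-ginsenoside Ro,C50H78O20,997.5001,[M-H]-,-1.30,,B22,
54,25.19,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6254,[M-H]-,-1.69,1077.5842;783.4910;621.4377,B23,
55,25.62,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6226,[M-H]-,-3.94,1077.5856;621.3146,B23,
56,25.67,Ginsenoside Rb2,C53H90O22,1123.5918,[M+HCOO]-,2.04,1077.5824;945.5402;915.5279;783.4881;765.4772;621.4359,B21,
57,26.24,Ginsenoside Rb3,C53H90O22,1123.5902,[M+HCOO]-,0.66,1077.5892;945.5474;915.5364;783.4912;621.4374;459.3830,B23,
58,26.77,Quinquenoside L1 or its isomer,C48H80O18,943.5262,[M-H]-,-1.04,,B22,
59,26.90,m-Ginsenoside Rc/Rb2 or m-Ginsenoside Rb3,C56H92O25,1163.5858,[M-H]-,0.23,1119.6012;1077.5910;1059.5793;915.5332;765.4795,B23,
60,27.00,Ginsenoside Ra1/Ra2 or its isomer,C58H98O26,1209.6257,[M-H]-,-1.38,,B23,
61,27.37,Notoginsenoside O or its isomer,C52H88O21,1093.5787,[M+HCOO]-,-0.15,,B22,
62,27.57,Yesanchinoside J or its isomer,C61H102O28,1281.6451,[M-H]-,-2.62,,B22,
63,27.87,Vinaginsenoside R3 or its isomer,C48H82O17,975.5511,[M+HCOO]-,-1.22,739.7635;576.8463;481.3275;324.4059,B22,
64,28.76,Ginsenoside Rd,C48H82O18,991.5497,[M+HCOO]-,2.55,945.5477;783.4920;765.480;621.4385;459.3882,B21,
65,30.28,AcO-ginsenoside Rd or its isomer,C50H84O19,987.5526,[M-H]-,-0.84,987.5518;945.5420;927.5342;783.4925;765.4773;621.4397;459.3808,B23,
66,31.41,Quinquenoside L14 or its isomer,C47H80O17,961.5370,[M+HCOO]-,0.27,915.5347;783.4907;709.1200;621.4368;434.0248,B22,
67,31.43,Ginsenoside Re2 or its isomer,C48H82O19,961.5403,[M-H]-,2.60,,B16,
68,31.55,Quinquenoside I or its isomer,C52H86O19,1059.5731,[M+HCOO]-,-0.27,,B22,
69,31.68,Quinquenoside I or its isomer,C52H86O19,1059.5852,[M+HCOO]-,11.10,,B22,
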