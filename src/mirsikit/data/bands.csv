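assignment,center,window_low,window_high
DNA,966,954,978
CH2OH (fixation artifact),1026,1014,1028
Glycogen,1030,1028,1032.5
DNA,1035,1032.5,1047
DNA,1082,1070,1094
Glycogen,1154,1142,1161
Proteins,1168,1161,1180
Amide III,1238,1226,1250
Amide III,1308,1296,1320
Proteins,1400,1388,1412
Proteins,1448,1436,1455
Lipids,1462,1455,1474
Amide II,1516,1504,1528
Amide II,1546,1534,1558
Amide I,1658,1646,1670
Lipids,1744,1732,1756
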