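frail
0.0779890862
-0.0917495547
0.1123581427
0.0021052531
-0.1030323173
-0.1364893432
0.2224197000
0.0515772004
-0.2274725603
0.1449207174
-0.1015455594
0.1460742721
0.2431662998
0.0711977921
-0.0791414023
0.1193206637
0.1448424055
0.2482804987
-0.1974378177
0.1341404141
0.1594286916
-0.1734781432
-0.1186131752
0.2080546020
0.1272293332
-0.1233676345
-0.2692851109
0.2453311268
-0.1165182299
-0.2252062752
-0.1237862521
0.1913828847
-0.2367135125
0.1461862507
-0.2022351056
-0.1215655158
0.1099311048
0.1864478181
-0.1939670416
-0.3123015557
-0.1312793962
-0.0899339856
0.1802439460
0.1456912235
-0.1140097987
0.1691747031
0.1994870355
-0.3039741265
-0.1476118408
0.2070920022
-0.0945360205
-0.1922953113
-0.2692739668
0.1600576394
-0.0218991532
0.1939083390
-0.2086084094
0.1717499381
-0.0872020952
-0.3321260138
-0.0672284315
-0.0602816252
0.0683410968
0.2254586050
-0.0708970034
0.0162057437
0.2314014437
0.0893480589
-0.1702844517
0.0328238169
-0.1925882233
-0.2351771326
0.1561557999
0.2266972074
-0.4040974601
-0.1217827527
-0.2144717528
-0.2292374758
-0.0975033901
0.1484535354
0.2076833926
-0.1558384075
-0.1528963325
0.2412056855
0.1472801128
-0.1995963093
-0.1719822952
-0.1042503626
0.1089001066
0.2382850518
0.2173000194
0.2390099911
0.2315091136
0.1175687338
0.2291184915
-0.0731550936
-0.0747075234
-0.0975850196
0.2009924564
-0.0004767455
-0.2099191252
0.1157895889
-0.0408014192
0.0051235824
0.1196167957
0.2449711499
-0.1818490821
-0.0279198694
-0.3493461947
-0.0523110899
-0.1414776476
0.1568995026
0.1705408557
-0.1856972018
0.0544775071
-0.0275745639
0.2126332337
-0.2318832951
-0.2195930171
-0.0347930265
0.2312396899
0.1797984598
-0.1581203957
-0.1625714253
0.0307520089
-0.1878510250
0.1138394851
-0.0002950512
0.0167756026
0.1753060678
0.0416031615
0.1941074180
0.1364879652
0.2157467221
-0.1634382196
-0.1275453614
-0.1023101878
0.0557061444
0.1922440121
0.0560038182
0.1619065191
-0.3527290451
0.0452315675
0.1338415217
0.1808141639
0.1218619767
0.1756643410
0.0602431930
-0.3172512916
-0.1767820532
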