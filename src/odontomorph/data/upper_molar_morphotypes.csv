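specimen,cohort,side,m1_c1c2_profile,m2_spur,m3_c1,abnormal_cusp
D1399,Jag1fl/fl,right,V-shape,-,reduced,
D1399,Jag1fl/fl,left,V-shape,-,-,
D1400,Jag1fl/fl,right,U-shape,no spur,-,
D1400,Jag1fl/fl,left,U-shape,-,-,c8M2
D1401,Jag1fl/fl,right,V-shape,-,reduced,c5M2
D1401,Jag1fl/fl,left,V-shape,-,-,"c5M1, c8M2"
D1402,Jag1fl/fl,right,U-shape,-,-,c8M2
D1402,Jag1fl/fl,left,U-shape,-,-,c8M2
D1404,Jag1fl/fl,right,U-shape,no spur,-,c5M2
D1404,Jag1fl/fl,left,U-shape,no spur,reduced,c8M2
D1405,Jag1fl/fl,right,U-shape,no spur,-,c8M2
D1405,Jag1fl/fl,left,V-shape,no spur,-,
D1406,Jag1fl/fl,right,V-shape,no spur,-,c8M2
D1406,Jag1fl/fl,left,V-shape,no spur,-,c8M2
D1407,Jag1fl/fl,right,V-shape,no spur,-,
D1407,Jag1fl/fl,left,V-shape,-,-,
D1408,Jag1fl/fl,right,U-shape,-,-,c8M2
D1408,Jag1fl/fl,left,U-shape,-,-,
D1409,Jag1fl/fl,right,U-shape,-,-,c8M1-2
D1409,Jag1fl/fl,left,V-shape,no spur,-,c8M2
D1413,Jag1fl/fl,right,U-shape,no spur,-,
D1413,Jag1fl/fl,left,U-shape,no spur,-,
D1414,Jag1fl/fl,right,U-shape,no spur,-,
D1414,Jag1fl/fl,left,V-shape,no spur,-,c8M1-2
D1415,Jag1fl/fl,right,U-shape,no spur,-,c8M1-2
D1415,Jag1fl/fl,left,U-shape,no spur,-,c8M1-2
D1433,Jag1fl/fl,right,U-shape,-,-,c8M2
D1433,Jag1fl/fl,left,V-shape,no spur,reduced,c8M1-2
D1434,Jag1fl/fl,right,U-shape,no spur,-,
D1434,Jag1fl/fl,left,U-shape,no spur,-,
D1435,Jag1fl/fl,right,V-shape,no spur,-,c8M2
D1435,Jag1fl/fl,left,V-shape,no spur,-,c8M1-2
D1436,Jag1fl/fl,right,U-shape,no spur,-,
D1436,Jag1fl/fl,left,U-shape,no spur,-,c8M2
D1439,Jag1fl/fl,right,U-shape,-,-,c8M2
D1439,Jag1fl/fl,left,V-shape,no spur,-,
D1440,Jag1fl/fl,right,V-shape,no spur,-,c8M2
D1440,Jag1fl/fl,left,U-shape,no spur,-,c5-8M2
D1443,Jag1fl/fl,right,V-shape,no spur,reduced,
D1443,Jag1fl/fl,left,U-shape,no spur,reduced,c8M1
D1444,Jag1fl/fl,right,V-shape,no spur,reduced,c5M2
D1444,Jag1fl/fl,left,V-shape,no spur,reduced,
M8,Jag1fl/fl,right,U-shape,-,big,c8M2
M8,Jag1fl/fl,left,U-shape,no spur,-,c8M3
M9,Jag1fl/fl,right,V-shape,no spur,reduced,
M9,Jag1fl/fl,left,U-shape,no spur,reduced,c8M2
M10,Jag1fl/fl,right,V-shape,no spur,reduced,c8M2
M10,Jag1fl/fl,left,V-shape,-,reduced,c8M1-2
M11,Jag1fl/fl,right,U-shape,-,reduced,
M11,Jag1fl/fl,left,U-shape,no spur,reduced,c8M1
M12,Jag1fl/fl,right,U-shape,-,reduced,
M12,Jag1fl/fl,left,U-shape,-,reduced,
M15,Jag1fl/fl,right,V-shape,-,-,
M15,Jag1fl/fl,left,V-shape,-,-,
M16,Jag1fl/fl,right,V-shape,no spur,reduced,c8M2
M16,Jag1fl/fl,left,U-shape,no spur,reduced,"c5M1, c8M2"
M18,Jag1fl/fl,right,U-shape,no spur,-,c8M2
M18,Jag1fl/fl,left,U-shape,-,reduced,c5-8M2
M19,Jag1fl/fl,right,U-shape,-,-,c8M2
M19,Jag1fl/fl,left,U-shape,no spur,-,c8M1
M21,Jag1fl/fl,right,U-shape,no spur,-,c8M1-2
M21,Jag1fl/fl,left,V-shape,-,-,c8M1-2
M22,Jag1fl/fl,right,U-shape,-,-,
M22,Jag1fl/fl,left,U-shape,-,-,
M23,Jag1fl/fl,right,U-shape,-,-,
M23,Jag1fl/fl,left,V-shape,no spur,reduced,c8M1-2
D1398,WT,right,V-shape,-,-,
D1398,WT,left,V-shape,-,-,
D1403,WT,right,V-shape,-,-,
D1403,WT,left,V-shape,-,-,
D1410,WT,right,V-shape,-,-,
D1410,WT,left,V-shape,-,-,
D1411,WT,right,V-shape,-,-,
D1411,WT,left,V-shape,-,-,
D1412,WT,right,V-shape,-,-,
D1412,WT,left,V-shape,-,-,
D1426,WT,right,V-shape,-,-,
D1426,WT,left,V-shape,-,-,
D1427,WT,right,V-shape,-,-,
D1427,WT,left,V-shape,-,-,
D1428,WT,right,V-shape,-,-,
D1428,WT,left,V-shape,-,-,
D1429,WT,right,V-shape,-,-,
D1429,WT,left,V-shape,-,-,
D1430,WT,right,V-shape,-,-,
D1430,WT,left,V-shape,-,-,
D1431,WT,right,V-shape,-,-,
D1431,WT,left,V-shape,-,-,
D1432,WT,right,V-shape,-,-,
D1432,WT,left,V-shape,-,-,
D1437,WT,right,V-shape,-,-,
D1437,WT,left,V-shape,-,-,
D1438,WT,right,V-shape,-,-,
D1438,WT,left,V-shape,-,-,
D1441,WT,right,V-shape,-,-,
D1441,WT,left,V-shape,-,-,
D1442,WT,right,V-shape,-,-,
D1442,WT,left,V-shape,-,-,
M13,WT,right,V-shape,-,-,
M13,WT,left,V-shape,-,-,
M14,WT,right,V-shape,-,-,
M14,WT,left,V-shape,-,-,
M17,WT,right,V-shape,-,-,
M17,WT,left,V-shape,-,-,
M20,WT,right,V-shape,-,-,
M20,WT,left,V-shape,-,-,
M24,WT,right,V-shape,-,-,
M24,WT,left,V-shape,-,-,
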