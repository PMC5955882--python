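# Default synthetic-morphology branch statistics (versioned fixture).
# Calibrated so the mTC total-lateral-length distribution peaks near
# 8,500 um and the synthetic populations reproduce the full-morphology
# input resistances; path_length_dist is the descriptive terminal
# path-length distribution implied by the growth rule (regenerated by
# brute-force resampling in make_fixtures).
MC:
  branch_length_dist:
    kind: lognormal
    params: {mean: 6.214608098422191, sd: 0.45}
  branching_prob: [0.85, 0.6, 0.3]
  min_diameter: 0.3
  n_lateral_dendrites_dist:
    kind: choice
    params:
      probs: null
      values: [6, 7, 8]
  path_length_dist:
    kind: empirical
    params:
      values: [311.11, 361.72, 434.46, 478.89, 520.62, 571.58, 598.37, 665.71, 691.39,
        709.31, 736.5, 759.49, 772.82, 788.57, 806.84, 826.16, 837.93, 849.35, 871.04,
        893.43, 912.65, 921.51, 935.71, 963.12, 970.67, 995.23, 1000.84, 1011.57,
        1026.78, 1040.26, 1051.61, 1068.39, 1083.2, 1108.85, 1121.79, 1134.28, 1142.25,
        1153.68, 1167.31, 1176.85, 1196.59, 1206.09, 1212.8, 1225.92, 1233.99, 1245.77,
        1254.54, 1265.61, 1275.24, 1280.58, 1294.7, 1299.54, 1310.91, 1329.1, 1339.51,
        1349.63, 1352.96, 1358.77, 1370.55, 1380.79, 1388.0, 1396.49, 1404.43, 1413.07,
        1423.68, 1436.4, 1445.69, 1452.12, 1465.01, 1470.37, 1480.71, 1491.14, 1495.42,
        1502.5, 1512.28, 1529.12, 1534.75, 1544.29, 1551.62, 1560.74, 1568.72, 1575.79,
        1580.47, 1585.63, 1590.46, 1598.99, 1604.11, 1613.48, 1621.13, 1626.07, 1633.28,
        1640.53, 1647.65, 1655.88, 1665.4, 1674.19, 1682.42, 1688.28, 1695.75, 1703.26,
        1707.82, 1714.03, 1728.2, 1734.01, 1746.36, 1757.75, 1762.94, 1768.5, 1774.13,
        1781.19, 1784.77, 1793.73, 1800.26, 1805.79, 1815.18, 1821.47, 1827.78, 1834.44,
        1842.65, 1847.42, 1858.49, 1866.68, 1875.53, 1883.61, 1891.58, 1901.97, 1913.64,
        1925.83, 1935.12, 1946.87, 1959.67, 1968.16, 1973.21, 1980.38, 1984.51, 1992.05,
        2002.91, 2014.16, 2028.31, 2038.11, 2049.12, 2056.76, 2067.59, 2072.72, 2081.09,
        2089.01, 2103.06, 2118.55, 2136.72, 2145.79, 2158.86, 2172.9, 2188.56, 2203.98,
        2213.14, 2223.05, 2230.26, 2242.79, 2257.81, 2270.62, 2277.17, 2291.89, 2312.67,
        2325.41, 2339.64, 2363.97, 2389.69, 2401.57, 2419.04, 2423.2, 2437.04, 2462.64,
        2469.08, 2479.4, 2494.74, 2507.68, 2531.08, 2543.49, 2562.81, 2579.38, 2607.38,
        2619.31, 2653.85, 2683.82, 2693.85, 2713.31, 2747.97, 2758.85, 2776.59, 2810.57,
        2847.43, 2875.61, 2922.11, 2945.4, 2987.12, 3044.44, 3151.11, 3236.52, 3329.85]
  stem_diameter: 3.2
  taper: 0.8
mTC:
  branch_length_dist:
    kind: lognormal
    params: {mean: 5.552959584921617, sd: 0.45}
  branching_prob: [0.85, 0.6, 0.3]
  min_diameter: 0.3
  n_lateral_dendrites_dist:
    kind: choice
    params:
      probs: [0.3, 0.4, 0.3]
      values: [4, 5, 6]
  path_length_dist:
    kind: empirical
    params:
      values: [160.53, 186.65, 224.18, 247.11, 268.64, 294.94, 308.76, 343.5, 356.76,
        366.0, 380.03, 391.9, 398.77, 406.9, 416.33, 426.3, 432.37, 438.26, 449.46,
        461.01, 470.93, 475.5, 482.83, 496.97, 500.87, 513.54, 516.43, 521.97, 529.82,
        536.77, 542.63, 551.29, 558.93, 572.16, 578.84, 585.29, 589.4, 595.3, 602.33,
        607.25, 617.44, 622.34, 625.81, 632.58, 636.74, 642.82, 647.34, 653.06, 658.03,
        660.78, 668.07, 670.57, 676.43, 685.82, 691.19, 696.41, 698.13, 701.13, 707.2,
        712.49, 716.21, 720.59, 724.69, 729.14, 734.62, 741.18, 745.98, 749.29, 755.95,
        758.71, 764.05, 769.43, 771.64, 775.29, 780.34, 789.03, 791.93, 796.85, 800.64,
        805.34, 809.46, 813.11, 815.52, 818.19, 820.68, 825.08, 827.72, 832.56, 836.5,
        839.05, 842.77, 846.52, 850.19, 854.43, 859.34, 863.88, 868.13, 871.15, 875.01,
        878.88, 881.24, 884.44, 891.75, 894.75, 901.12, 907.0, 909.68, 912.55, 915.45,
        919.1, 920.94, 925.57, 928.94, 931.79, 936.63, 939.88, 943.13, 946.57, 950.81,
        953.27, 958.98, 963.21, 967.77, 971.94, 976.06, 981.41, 987.44, 993.73, 998.52,
        1004.58, 1011.19, 1015.57, 1018.18, 1021.88, 1024.01, 1027.9, 1033.5, 1039.3,
        1046.61, 1051.66, 1057.35, 1061.29, 1066.88, 1069.52, 1073.84, 1077.93, 1085.18,
        1093.17, 1102.55, 1107.23, 1113.97, 1121.22, 1129.3, 1137.25, 1141.98, 1147.09,
        1150.81, 1157.28, 1165.03, 1171.64, 1175.02, 1182.62, 1193.34, 1199.91, 1207.25,
        1219.81, 1233.08, 1239.21, 1248.22, 1250.37, 1257.51, 1270.72, 1274.04, 1279.37,
        1287.28, 1293.96, 1306.04, 1312.44, 1322.41, 1330.96, 1345.41, 1351.57, 1369.39,
        1384.85, 1390.03, 1400.07, 1417.95, 1423.57, 1432.72, 1450.25, 1469.27, 1483.82,
        1507.81, 1519.83, 1541.35, 1570.93, 1625.97, 1670.04, 1718.2]
  stem_diameter: 2.2
  taper: 0.8
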