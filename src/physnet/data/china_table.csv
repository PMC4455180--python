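id,name,state,x,y,population,gdp,actual_traffic_flow
0,Beijing,Beijing,116.41,39.90,20190000,16251.9393,2019
1,Tianjin,Tianjin,117.20,39.08,13550000,11307.2828,1355
2,Shijiazhuang,Hebei Province,114.51,38.04,72410000,24515.7676,7241
3,Taiyuan,Shanxi Province,112.55,37.87,35930000,11237.5555,3593
4,Hohhot,Inner Mongolian Autonomous Region,111.75,40.84,24820000,14359.88,2482
5,Shenyang,Liaoning Province,123.43,41.81,43830000,22226.70,4383
6,Changchun,Jilin Province,125.32,43.82,27490000,10568.83,2749
7,Harbin,Heilongjiang Province,126.53,45.80,38430000,12582.00,3834
8,Shanghai,Shanghai,121.47,31.23,23470000,19195.69,2347
9,Nanjing,Jiangsu Province,118.78,32.06,78990000,49110.27,7899
10,Hangzhou,Zhejiang Province,120.15,30.27,54630000,32318.85,5463
11,Hefei,Anhui Province,117.28,31.86,59680000,15300.65,5968
12,Fuzhou,Fujian Province,119.30,26.08,37200000,17560.18,3720
13,Nanchang,Jiangxi Province,115.86,28.68,44880000,11702.82,4488
14,Jinan,Shandong Province,117.12,36.65,96370000,45361.85,9637
15,Zhengzhou,Henan Province,113.63,34.75,93880000,26931.03,9388
16,Wuhan,Hubei Province,114.31,30.59,57580000,19632.26,5758
17,Changsha,Hunan Province,112.94,28.23,65960000,19669.56,6596
18,Guangzhou,Guangdong Province,113.26,23.13,105050000,53210.28,10505
19,Nanning,Guangxi Province,108.37,22.82,46450000,11720.87,4645
20,Haikou,Hainan Province,110.32,20.04,8770000,2522.66,877
21,Chongqing,Chongqing,106.55,29.56,29190000,10011.37,2919
22,Chengdu,Sichuan Province,104.07,30.57,80500000,21026.68,8050
23,Guiyang,Guizhou Province,106.63,26.65,34690000,5701.84,3469
24,Kunming,Yunnan Province,102.83,24.88,46310000,8893.12,4631
25,Lhasa,Tibet Autonomous Region,91.14,29.65,3030000,605.83,303
26,Xian,Shaanxi Province,108.94,34.34,37430000,12512.30,3743
27,Lanzhou,Gansu Province,103.83,36.06,25640000,5020.37,2564
28,Xining,Qinghai Province,101.78,36.62,5680000,1670.44,568
29,Yinchuan,Ningxia Hui Autonomous Region,106.23,38.49,6390000,2102.21,639
30,Urumqi,Xinjiang Uyghur Autonomous Region,87.62,43.83,24820000,6610.05,2209
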