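compound_id,compound,cls,category,standard,wavelength_nm,CO-1,CO-2,CO-3,CO-4,CO-5,CO-6,CO-7,CO-C,CP-1,CP-2,CP-3,CP-4,CP-C,CI-1,CI-2,CI-3,CH-1,CH-2,CHO-C
1,Chlorogenic acid,phenolic_acid,CA,CA,340,1933.2/36.9,1634.0/40.7,243.6/2.8,4238.1/33.9,1393.3/56.4,1091.5/17.9,14724.5/102.7,5612.6/228.5,2217.8/59.6,949.0/35.0,836.3/12.6,927.5/18.2,78.7/4.3,1644.1/44.7,323.4/12.8,1331.8/16.1,2881.9/74.0,993.4/110.6,1492.6/8.3
2,Luteolin C-hexoside-O-hexoside (1),flavonoid,LG,VX,340,181.4/4.0,277.6/14.5,33.3/1.7,<LOQ,<LOQ,40.2/1.5,<LOQ,83.2/0.4,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
3,Isoorientin-2''-O-xyloside,flavonoid,LG,VX,340,455.7/9.8,884.0/11.1,196.9/3.0,<LOQ,284.5/6.3,69.7/1.3,<LOQ,612.2/9.7,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,1034.2/5.8,838.7/38.5,2066.8/28.8,<LOQ,<LOQ,53.5/1.6
4,Luteolin C-hexoside-O-hexoside (2),flavonoid,LG,VX,340,65.7/1.8,233.8/3.3,<LOQ,<LOQ,<LOQ,366.8/8.1,<LOQ,85.8/3.2,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,48.1/7.9,<LOQ,<LOQ,<LOQ,295.0/3.6
5,Isoorientin-4''-O-xyloside,flavonoid,LG,VX,340,105.1/10.5,370.2/11.5,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,204.2/12.2,<LOQ,<LOQ,<LOQ,<LOQ,22.4/1.2,67.2/8.2,43.0/4.3,112.4/1.6,<LOQ,<LOQ,755.4/21.1
6,Isoorientin,flavonoid,LG,VX,340,384.6/8.3,1077.7/10.2,40.2/3.3,6399.4/25.5,4187.9/119.8,160.9/1.5,5177.7/54.5,3661.7/74.0,1796.2/39.2,2127.9/54.4,1066.0/22.3,1993.5/20.3,187.7/1.2,491.7/4.0,652.9/39.9,2487.9/32.4,444.2/8.1,882.0/96.5,1085.9/15.9
7,Orientin,flavonoid,LG,VX,340,<LOQ,<LOQ,<LOQ,1117.6/9.7,1167.4/35.5,<LOQ,4523.8/44.9,<LOQ,1076.9/13.6,749.3/18.2,926.6/15.2,1562.5/19.4,24.1/0.9,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,337.7/5.2
8,Isoorientin-2''-O-rhamnoside,flavonoid,LG,VX,340,612.0/17.0,241.2/5.7,164.0/5.0,<LOQ,<LOQ,129.8/1.6,<LOQ,823.0/20.1,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,82.5/1.7,84.4/9.6,<LOQ,<LOQ,<LOQ,<LOQ
9,Luteolin C-hexoside-O-pentoside,flavonoid,LG,VX,340,84.8/3.7,145.1/4.6,23.9/4.0,<LOQ,<LOQ,<LOQ,<LOQ,119.7/7.7,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,93.6/4.5,59.1/7.4,309.4/9.3,<LOQ,<LOQ,79.1/1.1
10,Isovitexin-2''-O-glucoside,flavonoid,AG,VX,340,240.4/6.7,465.3/8.4,269.6/2.4,<LOQ,112.1/7.4,315.3/8.4,<LOQ,118.3/5.9,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,86.9/2.0,47.9/1.7,<LOQ,<LOQ,<LOQ,146.8/6.4
11,Isovitexin-2''-O-xyloside,flavonoid,AG,VX,340,761.4/19.7,1671.4/26.2,1936.3/11.4,<LOQ,1044.7/36.3,2142.9/71.9,<LOQ,787.1/16.8,266.5/3.1,410.0/19.6,<LOQ,231.2/7.1,26.9/0.6,3213.6/61.0,2416.4/143.3,1677.5/23.8,<LOQ,<LOQ,390.3/7.7
12,Vitexin,flavonoid,AG,VX,340,170.1/5.9,<LOD,<LOQ,<LOQ,98.0/1.3,<LOQ,295.2/3.6,<LOQ,198.2/2.1,457.4/37.2,625.2/2.5,457.3/2.7,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
13,Apigenin C-hexoside-O-pentoside,flavonoid,AG,VX,340,156.2/4.1,511.8/6.5,80.6/1.5,<LOQ,<LOQ,233.4/3.0,<LOQ,138.8/4.3,<LOQ,<LOQ,<LOQ,<LOQ,42.4/2.6,110.5/17.1,79.5/13.3,<LOQ,<LOQ,<LOQ,<LOQ
14,Diosmetin C-hexoside-O-pentoside,flavonoid,DG,VX,340,58.0/1.0,134.1/1.9,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,73.0/1.1,102.1/5.9,237.0/4.3,<LOQ,<LOQ,506.7/6.2
15,Isovitexin 2''-O-rhamnoside,flavonoid,AG,VX,340,364.4/8.5,424.8/7.8,1057.6/5.2,<LOQ,1376.9/36.8,1356.7/30.8,<LOQ,<LOQ,1107.2/4.7,2338.1/103.2,3379.7/51.4,2132.5/25.3,<LOQ,587.1/7.2,672.4/18.2,<LOQ,<LOQ,<LOQ,<LOQ
16,Apigenin C-hexoside-O-xyloside,flavonoid,AG,VX,340,177.7/5.1,436.9/5.2,287.5/2.5,<LOQ,<LOQ,179.1/4.7,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,329.4/8.4,219.5/21.0,<LOQ,<LOQ,<LOQ,<LOQ
17,Isovitexin,flavonoid,AG,VX,340,<LOQ,<LOQ,<LOQ,502.8/2.3,<LOQ,<LOQ,991.2/12.1,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,121.2/1.3,<LOQ,<LOQ,795.6/12.5,<LOQ,<LOQ,<LOQ
18,Diosmetin-C-hexoside-O-deoxyhexoside,flavonoid,DG,VX,340,<LOQ,<LOQ,38.1/0.7,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
19,Diosmetin-C-hexoside,flavonoid,DG,VX,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,338.3/14.2,<LOQ,21.2/0.6,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
20,Luteolin-O-malonyl-C-hexoside (1),flavonoid,LMG,VX,340,<LOQ,<LOQ,<LOQ,318.8/1.4,251.0/59.2,<LOQ,<LOQ,<LOQ,457.8/11.1,444.2/4.5,<LOQ,540.9/3.4,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
21,Luteolin-O-malonyl-C-hexoside (2),flavonoid,LMG,VX,340,<LOQ,<LOQ,<LOQ,1486.3/14.2,651.1/17.0,<LOQ,1622.9/16.7,<LOQ,426.8/3.4,631.3/24.1,314.0/31.6,332.4/3.9,<LOQ,<LOQ,<LOQ,<LOQ,144.9/3.6,173.6/20.7,<LOQ
22,Apigenin-O-malonyl-C-hexoside (1),flavonoid,AMG,VX,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,244.2/69.0,70.4/0.4,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
23,Apigenin-O-deoxyhexoside-O-malonyl-C-hexoside (1),flavonoid,AMG,VX,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,172.1/12.0,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
24,Apigenin-O-malonyl-C-hexoside (2),flavonoid,AMG,VX,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,124.9/1.7,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
25,Apigenin-O-deoxyhexoside-O-malonyl-C-hexoside (2),flavonoid,AMG,VX,340,<LOQ,<LOQ,<LOQ,657.8/6.7,171.3/4.5,<LOQ,<LOQ,<LOQ,<LOQ,141.4/6.2,196.3/2.5,58.5/1.5,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
26,Apigenin-O-malonyl-C-hexoside (3),flavonoid,AMG,VX,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,696.2/4.1,<LOQ,148.4/12.4,614.9/23.4,478.5/5.4,116.6/1.1,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
27,Quercetin O-hexoside-O-deoxyhexoside,flavonoid,QG,RU,340,<LOQ,<LOQ,<LOQ,939.7/18.9,<LOQ,<LOQ,<LOQ,2988.5/180.1,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,2884.2/102.9,1491.5/171.0,<LOQ
28,Rutin,flavonoid,QG,RU,340,72.9/3.4,112.9/3.4,<LOQ,681.1/9.7,168.4/3.4,<LOQ,704.7/4.2,1041.2/25.1,<LOQ,<LOQ,<LOQ,<LOQ,53.5/1.2,<LOQ,<LOQ,<LOQ,3949.2/116.7,2105.6/218.6,<LOQ
29,Quercetin O-hexoside (1),flavonoid,QG,RU,340,<LOQ,<LOQ,<LOQ,352.1/20.6,<LOQ,<LOQ,<LOQ,519.2/98.6,<LOQ,<LOQ,<LOQ,294.9/9.0,<LOQ,127.4/2.8,93.3/2.5,800.7/21.2,1388.9/37.0,1105.2/121.7,<LOQ
30,Quercetin O-hexoside (2),flavonoid,QG,RU,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,655.6/3.8,524.8/19.9,161.3/4.5,<LOQ,<LOQ,23.9/0.8,453.0/8.2,248.1/5.0,825.8/28.4,4146.0/144.3,3957.0/43.0,<LOQ
31,Quercetin O-pentoside (1),flavonoid,QG,RU,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,226.9/7.5,165.5/18.4,<LOQ
32,Quercetin O-pentoside (2),flavonoid,QG,RU,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,423.5/8.0,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,215.7/8.1,1474.8/47.9,1040.1/115.2,<LOQ
33,Quercetin O-hexoside-O-hexoside,flavonoid,QG,RU,340,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,240.1/17.1,179.1/25.3,<LOQ
34,Flavonolignan 1,flavonolignan,FL,VX,390,202.6/18.0,241.1/22.0,144.1/8.1,<LOQ,205.6/9.0,510.2/2.9,138.5/13.2,98.0/6.8,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
35,Flavonolignan 2,flavonolignan,FL,VX,390,799.1/,982.5/97.8,609.3/27.2,280.9/6.7,864.0/42.8,1857.1/61.8,653.0/40.6,688.8/44.0,<LOQ,<LOQ,260.3/17.1,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ
36,Flavonolignan 3,flavonolignan,FL,VX,390,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,<LOQ,57.1/8.0,121.3/6.0,<LOQ,<LOQ,<LOQ,213.9/8.0,<LOQ,179.1/4.5,227.8/20.3,<LOQ,<LOQ,<LOQ,<LOQ
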