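# Per-class land-cover areas for Central Asia, units of 10^4 ha, as published
# (1995/2005/2015 observed from the 300 m CCI-LC product; 2025/2035 CA-Markov
# projections). The total is constant at 40,010.48 x 10^4 ha.
year,class,area_1e4_ha
1995,cropland,7595.03
1995,forestland,800.90
1995,grassland,20560.52
1995,wetland,121.14
1995,urban,27.57
1995,bare,9563.26
1995,water,1342.06
2005,cropland,8591.77
2005,forestland,801.05
2005,grassland,19810.87
2005,wetland,121.69
2005,urban,60.21
2005,bare,9449.80
2005,water,1175.08
2015,cropland,8814.59
2015,forestland,800.48
2015,grassland,19948.14
2015,wetland,125.25
2015,urban,89.19
2015,bare,9183.36
2015,water,1049.48
2025,cropland,9051.58
2025,forestland,799.49
2025,grassland,20077.26
2025,wetland,125.25
2025,urban,90.82
2025,bare,8926.89
2025,water,939.17
2035,cropland,9273.75
2035,forestland,798.42
2035,grassland,20203.47
2035,wetland,128.41
2035,urban,116.47
2035,bare,8662.38
2035,water,827.58
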