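# Synthetic best-effort legend mapping CCI-LC-style raw codes to the seven
# working classes. The exact mapping used to build the packaged Central Asia
# area table was never published; this file is a documented stand-in that
# follows the CCI-LC v2 code book conventions. Edit to taste.
raw_code,class_name
0,nodata
10,cropland
11,cropland
12,cropland
20,cropland
30,cropland
40,grassland
50,forestland
60,forestland
61,forestland
62,forestland
70,forestland
71,forestland
72,forestland
80,forestland
81,forestland
82,forestland
90,forestland
100,forestland
110,grassland
120,grassland
121,grassland
122,grassland
130,grassland
140,grassland
150,grassland
151,grassland
152,grassland
153,grassland
160,wetland
170,wetland
180,wetland
190,urban
200,bare
201,bare
202,bare
210,water
220,bare
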