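# Benefit-transfer value coefficients for Central Asia, US$ per ha per year.
# Rows = land-cover classes, columns = nine ecosystem service functions.
# Source: published Central Asia assessment built on the de Groot et al. global
# unit-value model; the bare-land row is zero by construction.
class,food_production,raw_material,gas_regulation,climate_regulation,water_regulation,soil_formation,waste_treatment,biodiversity,recreation
cropland,2323,219,0,411,400,639,397,1096,82
forestland,299,181,0,152,191,107,120,1097,990
grassland,1192,54,9,40,63,46,75,2494,193
wetland,614,539,0,3474,6014,4320,3015,3502,4203
urban,0,0,0,905,16,0,0,0,5740
bare,0,0,0,0,0,0,0,0,0
water,106,0,0,0,9322,0,918,0,2166
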