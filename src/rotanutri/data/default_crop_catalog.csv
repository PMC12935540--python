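crop_name,functional_type,edible,forage_only,f_H2O,alpha,f_ref,gamma_calorie,gamma_carb,gamma_protein,gamma_fat,retail_product
winter_wheat,cereal,True,False,0.12,0.75,1.0,0.00364,0.763,0.103,0.0098,wheat_flour
spring_wheat,cereal,True,False,0.12,0.75,1.0,0.00364,0.763,0.103,0.0098,wheat_flour
spring_barley,cereal,True,False,0.10,0.60,1.0,0.00352,0.778,0.099,0.0123,pearled_barley
winter_barley,cereal,True,False,0.10,0.60,1.0,0.00352,0.778,0.099,0.0123,pearled_barley
oat,cereal,True,False,0.09,0.55,1.0,0.00389,0.663,0.169,0.0690,oatmeal
rye,cereal,True,False,0.11,0.80,1.0,0.00349,0.758,0.103,0.0160,rye_flour
triticale,cereal,True,False,0.11,0.78,1.0,0.00355,0.760,0.105,0.0140,triticale_flour
maize_grain,cereal,True,False,0.11,0.80,1.0,0.00361,0.766,0.069,0.0390,maize_flour
pea,annual_legume,True,False,0.11,1.00,1.0,0.00341,0.630,0.236,0.0120,dried_peas
faba_bean,annual_legume,True,False,0.11,1.00,1.0,0.00341,0.580,0.262,0.0150,dried_beans
lupin,annual_legume,True,False,0.10,1.00,1.0,0.00371,0.402,0.364,0.0970,dried_lupins
soybean,annual_legume,True,False,0.09,1.00,1.0,0.00446,0.302,0.365,0.1990,dried_soybeans
potato,annual_broadleaf,True,False,0.79,1.00,0.75,0.00077,0.175,0.020,0.0009,raw_potatoes
sugar_beet,annual_broadleaf,True,False,0.00,0.14,1.0,0.00387,0.998,0.000,0.0000,sugar
swede,annual_broadleaf,True,False,0.90,1.00,0.85,0.00037,0.086,0.011,0.0016,raw_swede
oilseed_rape,annual_broadleaf,True,False,0.00,0.40,1.0,0.00884,0.000,0.000,1.0000,rapeseed_oil
sunflower,annual_broadleaf,True,False,0.00,0.40,1.0,0.00884,0.000,0.000,1.0000,sunflower_oil
ley,ley,False,True,,,,,,,,forage
grass_ley,ley,False,True,,,,,,,,forage
clover_grass_ley,ley,False,True,,,,,,,,forage
ryegrass,ley,False,True,,,,,,,,forage
forage_rape,annual_broadleaf,False,True,,,,,,,,forage
silage_maize,cereal,False,True,,,,,,,,forage
fallow,fallow,False,False,,,,,,,,none
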