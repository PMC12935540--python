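product_name,unit,dm_to_product,f_H2O,f_ref,gamma_calorie,gamma_carb,gamma_protein,gamma_fat
whole_milk,l,1.05,0.88,1.0,0.000628,0.0494,0.0330,0.0340
boneless_beef,kg,0.047,0.73,1.0,0.002500,0.0000,0.1860,0.1940
biofuel,kg,0.0,0.00,0.0,0.000000,0.0000,0.0000,0.0000
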