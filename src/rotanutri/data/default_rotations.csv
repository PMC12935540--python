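rotation_id,year_index,crop_name,use
R1M_wheat,0,winter_wheat,food
R1C_cereals,0,winter_wheat,food
R1C_cereals,1,spring_barley,food
R1C_cereals,2,oat,food
R2_oilseed,0,winter_wheat,food
R2_oilseed,1,oilseed_rape,food
R2_oilseed,2,winter_wheat,food
R2_oilseed,3,spring_barley,food
R3_ley,0,spring_barley,food
R3_ley,1,ley,forage
R3_ley,2,ley,forage
R3_ley,3,winter_wheat,food
R3_ley,4,pea,food
R1M_fallow,0,winter_wheat,food
R1M_fallow,1,fallow,none
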