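food_id,w_usda_g,v_usda_cm3,carbs_per100g,protein_per100g,fat_per100g,kcal_per100g
moussaka,250.0,240.0,8.6,7.1,10.8,160.0
pastitsio,260.0,245.0,14.2,8.3,9.5,178.0
greek_salad,150.0,210.0,4.5,2.1,8.9,105.0
gigantes,220.0,230.0,15.8,6.4,6.2,142.0
dolmades,180.0,170.0,12.1,3.5,7.4,130.0
spanakopita,140.0,160.0,17.5,5.6,13.2,215.0
souvlaki,160.0,150.0,2.4,19.8,9.6,180.0
beefsteak,170.0,155.0,0.0,24.5,12.3,210.0
fish_roe_dip,120.0,115.0,9.8,4.2,28.5,320.0
rice_pilaf,200.0,220.0,28.4,3.1,4.7,168.0
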