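item_id,description,serving_label,energy_kcal,protein_g,fat_sat_g,fat_unsat_g,carb_g,serving_weight_g,vitamin_c_mg,calcium_mg
oatmeal,Oatmeal with brown sugar,1 cup,220,6,0.8,2.2,42,240,0,120
scrambled_eggs,Scrambled eggs,2 eggs,180,12,4.5,6.0,2,120,0,60
toast_wheat,Whole wheat toast with margarine,1 slice,110,3,0.9,2.5,16,35,0,30
orange_juice,Orange juice,120 mL,55,1,0,0,13,124,48,12
milk_2pct,2% milk,1 cup,120,8,3.0,1.8,12,244,2,290
coffee,Black coffee,180 mL,2,0,0,0,0,180,0,4
chicken_breast,Baked chicken breast,3 oz,165,31,1.0,2.6,0,85,0,15
mashed_potato,Mashed potatoes with gravy,0.5 cup,140,3,2.0,2.5,20,120,10,25
green_beans,Seasoned green beans,0.5 cup,40,2,0.1,1.2,7,65,8,35
dinner_roll,Dinner roll,1 roll,90,3,0.6,1.5,15,30,0,20
apple_juice,Apple juice,120 mL,58,0,0,0,14,125,45,9
beef_stew,Beef stew,1 cup,260,18,4.0,6.0,18,245,6,30
rice_white,Steamed white rice,0.5 cup,103,2,0.1,0.2,22,80,0,8
fruit_cup,Mixed fruit cup,0.5 cup,70,0,0,0,18,125,30,10
pudding_van,Vanilla pudding,0.5 cup,150,3,1.5,1.0,26,115,0,100
broth_chicken,Chicken broth,1 cup,15,2,0.2,0.3,1,240,0,10
gelatin,Fruit gelatin,0.5 cup,80,1,0,0,19,120,0,2
ice_cream_van,Vanilla ice cream,0.5 cup,140,2,4.5,2.5,16,66,0,85
tea,Hot tea,180 mL,2,0,0,0,0,180,0,0
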