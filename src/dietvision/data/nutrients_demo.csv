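key,kcal_per_100ml,cho_g,pro_g,fat_g
tomato_rice,129,26.0,2.6,1.2
fried_rice,163,27.0,4.0,4.0
penne_tomato,112,20.0,4.0,1.6
spaghetti_pesto,155,20.0,5.0,6.0
roast_chicken,170,0.0,27.0,6.5
beef_stew,120,5.0,12.0,5.5
grilled_salmon,190,0.0,22.0,11.0
fish_cakes,155,14.0,10.0,7.0
steamed_broccoli,35,6.0,2.8,0.4
glazed_carrots,55,11.0,0.8,1.0
fruit_salad,50,12.0,0.6,0.2
berry_pudding,95,18.0,2.5,1.5
meat,145,2.5,19.5,6.0
vegetables,45,8.5,1.8,0.7
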