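fine,hyper2,hyper1,nutrient_key
tomato_rice,rice_dishes,staples,tomato_rice
fried_rice,rice_dishes,staples,fried_rice
penne_tomato,pasta_dishes,staples,penne_tomato
spaghetti_pesto,pasta_dishes,staples,spaghetti_pesto
roast_chicken,meat,protein,roast_chicken
beef_stew,meat,protein,beef_stew
grilled_salmon,fish,protein,grilled_salmon
fish_cakes,fish,protein,fish_cakes
steamed_broccoli,vegetables,plants,steamed_broccoli
glazed_carrots,vegetables,plants,glazed_carrots
fruit_salad,fruit_desserts,plants,fruit_salad
berry_pudding,fruit_desserts,plants,berry_pudding
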