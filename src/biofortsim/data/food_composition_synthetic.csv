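food_item,zinc_mg_per_100g,energy_kcal_per_100g
rice,1.7,346
wheat_flour,1.6,350
fresh_vegetables,0.4,25
root_vegetable,0.3,80
pickled_vegetables,0.5,30
pork,2.1,395
beef_lamb,4.7,190
poultry,1.5,167
liver,5.8,129
fish,1.2,110
eggs,1.1,144
tofu,1.2,82
whole_grains,2.5,340
fruits,0.2,52
juice,0.1,45
milk,0.4,54
yoghurt,0.5,72
milk_powder,3.1,480
cake,0.7,350
nuts,3.0,570
beer,0.05,32
alcohol,0.2,250
beverage,0.03,40
deep_fried_products,1.0,280
cheese,3.5,330
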