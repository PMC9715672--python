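source,category,kind,target,fraction,rule,split_group
aropaj,Pasture,predicts,pasture,1.0,pasture,
aropaj,Pasture,pft,c3_natural_grass,0.9,,c3_c4_grass
aropaj,Pasture,pft,c4_natural_grass,0.1,,c3_c4_grass
aropaj,Rangeland,predicts,rangeland,1.0,none,
aropaj,Rangeland,pft,c3_natural_grass,0.9,,c3_c4_grass
aropaj,Rangeland,pft,c4_natural_grass,0.1,,c3_c4_grass
aropaj,Urban,predicts,urban,1.0,none,
aropaj,Urban,pft,bare_soil,1.0,,
aropaj,Other ecosystem,predicts,primary,0.5,none,primary_secondary
aropaj,Other ecosystem,predicts,secondary,0.5,none,primary_secondary
aropaj,Other ecosystem,pft,bare_soil,1.0,,
aropaj,Forest,predicts,primary,0.5,none,primary_secondary
aropaj,Forest,predicts,secondary,0.5,none,primary_secondary
aropaj,Forest,pft,forest,1.0,,
aropaj,Durum wheat,predicts,annual,1.0,yield,
aropaj,Durum wheat,pft,c3_winter_crop,1.0,,
aropaj,Tender wheat,predicts,annual,1.0,yield,
aropaj,Tender wheat,pft,c3_winter_crop,1.0,,
aropaj,Winter barley,predicts,annual,1.0,yield,
aropaj,Winter barley,pft,c3_summer_crop,1.0,,
aropaj,Spring barley,predicts,annual,1.0,yield,
aropaj,Spring barley,pft,c3_summer_crop,1.0,,
aropaj,Oats,predicts,annual,1.0,yield,
aropaj,Oats,pft,c3_summer_crop,1.0,,
aropaj,Other cereals,predicts,annual,1.0,yield,
aropaj,Other cereals,pft,c3_summer_crop,1.0,,
aropaj,Rice,predicts,annual,1.0,yield,
aropaj,Rice,pft,c3_summer_crop,1.0,,
aropaj,Maize,predicts,annual,1.0,yield,
aropaj,Maize,pft,c4_summer_crop,1.0,,
aropaj,Fallow,predicts,annual,1.0,minimal,
aropaj,Fallow,pft,c3_natural_grass,1.0,,
aropaj,Beetroot,predicts,annual,1.0,yield,
aropaj,Beetroot,pft,c3_summer_crop,1.0,,
aropaj,Rapeseed,predicts,annual,1.0,yield,
aropaj,Rapeseed,pft,c3_winter_crop,1.0,,
aropaj,Sunflower,predicts,annual,1.0,yield,
aropaj,Sunflower,pft,c3_summer_crop,1.0,,
aropaj,Soybean,predicts,nfixing,1.0,yield,
aropaj,Soybean,pft,c3_natural_grass,1.0,,
aropaj,Other legumes,predicts,nfixing,1.0,yield,
aropaj,Other legumes,pft,c3_natural_grass,1.0,,
aropaj,Potato,predicts,annual,1.0,yield,
aropaj,Potato,pft,c3_summer_crop,1.0,,
aropaj,Perennial,predicts,perennial,1.0,yield,
aropaj,Perennial,pft,c3_summer_crop,1.0,,
nlu,Cassava,predicts,annual,1.0,yield,
nlu,Cassava,pft,c3_natural_grass,0.9,,c3_c4_grass
nlu,Cassava,pft,c4_natural_grass,0.1,,c3_c4_grass
nlu,Fieldpea,predicts,nfixing,1.0,yield,
nlu,Fieldpea,pft,c3_summer_crop,1.0,,
nlu,Groundnut,predicts,nfixing,1.0,yield,
nlu,Groundnut,pft,c3_summer_crop,1.0,,
nlu,Maize,predicts,annual,1.0,yield,
nlu,Maize,pft,c4_summer_crop,1.0,,
nlu,Millet,predicts,annual,1.0,yield,
nlu,Millet,pft,c3_summer_crop,1.0,,
nlu,Rapeseed,predicts,annual,1.0,yield,
nlu,Rapeseed,pft,c3_winter_crop,1.0,,
nlu,Rice,predicts,annual,1.0,yield,
nlu,Rice,pft,c3_summer_crop,1.0,,
nlu,Soybean,predicts,nfixing,1.0,yield,
nlu,Soybean,pft,c3_summer_crop,1.0,,
nlu,Sugarbeet,predicts,annual,1.0,yield,
nlu,Sugarbeet,pft,c3_summer_crop,1.0,,
nlu,Sunflower,predicts,annual,1.0,yield,
nlu,Sunflower,pft,c3_summer_crop,1.0,,
nlu,Wheat,predicts,annual,1.0,yield,
nlu,Wheat,pft,c3_winter_crop,1.0,,
nlu,Other,predicts,annual,0.8,yield,annual_perennial
nlu,Other,predicts,perennial,0.2,yield,annual_perennial
nlu,Other,pft,bare_soil,1.0,,
nlu,Pasture,predicts,pasture,0.8,pasture,pasture_rangeland
nlu,Pasture,predicts,rangeland,0.2,none,pasture_rangeland
nlu,Pasture,pft,c3_natural_grass,0.9,,c3_c4_grass
nlu,Pasture,pft,c4_natural_grass,0.1,,c3_c4_grass
nlu,Forest,predicts,primary,0.5,none,primary_secondary
nlu,Forest,predicts,secondary,0.5,none,primary_secondary
nlu,Forest,pft,forest,1.0,,
nlu,Urban,predicts,urban,1.0,none,
nlu,Urban,pft,bare_soil,1.0,,
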