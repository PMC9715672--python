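family,indicator,unit,baseline,halving_n
abandonment,bii,percent,78.7,80.1
abandonment,sr,percent,83.7,85.7
abandonment,npp,MtC_per_yr,2102.84,2141.29
abandonment,soil_c,MtC,20706.55,21720.68
abandonment,biomass_c,MtC,11300.24,11605.51
extensification,bii,percent,81,82
extensification,sr,percent,81,80.5
extensification,npp,MtC_per_yr,2020.10,2017.39
extensification,soil_c,MtC,19487.78,19390.67
extensification,biomass_c,MtC,15541.46,15514.08
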