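study_id,site_id,latitude,ecosystem,ph_reported,ph_medium,n_rate,emission_fertilized,emission_control,replicates,map_mm,mat_c,soc,tn,sand_pct,silt_pct,clay_pct
Smith2005,Smith2005-1,51.2,cropland,6.2,H2O,150,2.45,0.90,3,650,9.5,18.2,1.6,35,40,25
Smith2005,Smith2005-1,51.2,cropland,6.2,H2O,300,4.10,0.90,3,650,9.5,18.2,1.6,35,40,25
Li2012,Li2012-1,28.1,cropland,5.4,CaCl2,220,3.80,1.10,4,1450,17.2,12.4,1.1,,,
Ngetich2017,Ngetich2017-1,-0.4,grassland,5.9,H2O,100,1.75,0.65,3,900,19.0,,,,,
Berg2009,Berg2009-2,60.5,forest,4.8,KCl,50,0.42,0.30,5,550,4.1,45.0,2.2,,,
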