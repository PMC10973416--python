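study_id,sample_id,gene,copies_per_g,ph_h2o,n2o_flux,ecosystem
Chen2018,Chen2018-a,nirK,2.4e7,6.1,38.5,cropland
Chen2018,Chen2018-a,nirS,1.8e7,6.1,38.5,cropland
Chen2018,Chen2018-a,nosZ clade I,5.1e6,6.1,38.5,cropland
Chen2018,Chen2018-a,nosZ clade II,8.9e6,6.1,38.5,cropland
Jones2015,Jones2015-b,nirK,6.2e6,7.4,12.0,grassland
Jones2015,Jones2015-b,nirS,9.0e6,7.4,12.0,grassland
Jones2015,Jones2015-b,nosZI,7.7e6,7.4,12.0,grassland
Hallin2011,Hallin2011-c,AOA_amoA,3.3e7,5.2,,grassland
Hallin2011,Hallin2011-c,AOB_amoA,4.1e6,5.2,,grassland
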