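sample_id,acetylene,soil_dry_mass,bottle_volume,temperature_c,ph_h2o,time_h,ppm
GN-A0-1-c2h2,1,0.005,0.1,25,6.0,2,9.06
GN-A0-1-c2h2,1,0.005,0.1,25,6.0,4,17.79
GN-A0-1-c2h2,1,0.005,0.1,25,6.0,6,26.52
GN-A0-1-open,0,0.005,0.1,25,6.0,2,7.10
GN-A0-1-open,0,0.005,0.1,25,6.0,4,13.87
GN-A0-1-open,0,0.005,0.1,25,6.0,6,20.64
GY-A4-3-c2h2,1,0.005,0.1,25,7.2,2,10.50
GY-A4-3-c2h2,1,0.005,0.1,25,7.2,4,20.67
GY-A4-3-c2h2,1,0.005,0.1,25,7.2,6,30.84
GY-A4-3-open,0,0.005,0.1,25,7.2,2,7.24
GY-A4-3-open,0,0.005,0.1,25,7.2,4,14.14
GY-A4-3-open,0,0.005,0.1,25,7.2,6,21.04
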