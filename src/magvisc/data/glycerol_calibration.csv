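concentration_wt_pct,viscosity_mpa_s,density_kg_m3,resonant_frequency_hz,resonant_frequency_sd_hz,resonant_amplitude_mv,resonant_amplitude_sd_mv
0,1.01,998.23,120898.3,9.1,13.8837,0.0350
10,1.31,1022.10,120643.3,17.3,13.2270,0.0561
20,1.76,1046.90,120308.3,23.1,12.2919,0.0563
30,2.50,1072.70,119950.0,13.1,11.6586,0.0227
40,3.72,1099.30,119441.7,19.0,11.0223,0.0415
50,6.00,1126.30,118940.0,24.2,10.4544,0.0221
60,10.80,1153.80,118470.0,28.2,8.5304,0.0167
70,22.50,1181.25,117686.4,23.4,7.8858,0.0194
80,60.10,1208.50,116390.5,30.1,5.5546,0.0029
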