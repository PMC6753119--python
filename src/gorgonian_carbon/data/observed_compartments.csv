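species,depth_zone,n_colonies,biomass_g_afdm,daily_ingestion_g_c,daily_respiration_g_c,spring_flux_g_c,annual_sink_g_c
Paramuricea clavata,shallow,269,1269.66,10.04,5.14,441.35,57.42
Paramuricea clavata,deep,366,1258.64,9.73,3.40,570.18,61.36
Eunicella singularis,shallow,2229,1629.15,36.40,4.28,2890.24,322.77
Eunicella singularis,deep,2162,627.37,7.80,0.85,625.99,236.60
Leptogorgia sarmentosa,shallow,23,6.46,0.06,0.02,3.17,1.18
Leptogorgia sarmentosa,deep,35,9.61,0.09,0.03,5.58,1.78
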