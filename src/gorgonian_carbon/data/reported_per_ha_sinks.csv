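species,per_ha_sink_kg_c_ha_yr
Paramuricea clavata,2.58
Eunicella singularis,8.90
Leptogorgia sarmentosa,0.02
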