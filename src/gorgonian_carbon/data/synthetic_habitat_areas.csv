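# SYNTHETIC habitat-area table for tests and examples.  The mapped
# per-assemblage suitable areas of the study region are not public;
# these hectare values are invented placeholders with realistic
# magnitudes, not measurements.
assemblage,area_ha,zone,species_list
Vertical coralligenous,12.0,shallow,Paramuricea clavata;Eunicella singularis;Leptogorgia sarmentosa
Platform coralligenous,9.0,deep,Paramuricea clavata;Eunicella singularis;Leptogorgia sarmentosa
Photophilic algal communities,25.0,shallow,Eunicella singularis;Leptogorgia sarmentosa
Precoralligenous,18.0,shallow,Eunicella singularis
Littoral sandy mud,30.0,shallow,Leptogorgia sarmentosa
Littoral medium and coarse sand,22.0,shallow,Leptogorgia sarmentosa
Detrital littoral sands,40.0,deep,Leptogorgia sarmentosa
Detrital littoral sandy mud,35.0,deep,Leptogorgia sarmentosa
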