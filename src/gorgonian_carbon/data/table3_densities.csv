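species,assemblage,zone,total_density,total_sd,n_total,patch_density,patch_sd,n_patch
Paramuricea clavata,Vertical coralligenous,shallow,0.423,1.562,376,3.698,3.063,43
Paramuricea clavata,Platform coralligenous,deep,1.000,2.945,118,4.370,4.871,27
Eunicella singularis,Photophilic algal communities,shallow,0.323,1.840,93,2.000,4.318,15
Eunicella singularis,Precoralligenous,shallow,3.129,6.200,167,5.559,7.413,94
Eunicella singularis,Vertical coralligenous,shallow,1.737,4.109,376,4.213,5.533,155
Eunicella singularis,Platform coralligenous,deep,6.631,8.532,118,9.543,8.776,82
Leptogorgia sarmentosa,Photophilic algal communities,shallow,0.005,0.052,93,0.500,,1
Leptogorgia sarmentosa,Precoralligenous,shallow,0.021,0.149,167,0.875,0.479,4
Leptogorgia sarmentosa,Vertical coralligenous,shallow,0.013,0.109,376,0.714,0.393,7
Leptogorgia sarmentosa,Platform coralligenous,deep,0.017,0.112,118,0.667,0.289,3
Leptogorgia sarmentosa,Littoral sandy mud,shallow,0.008,0.063,64,0.500,,1
Leptogorgia sarmentosa,Littoral medium and coarse sand,shallow,0.013,0.081,113,0.500,0.000,3
Leptogorgia sarmentosa,Detrital littoral sands,deep,0.015,0.105,423,0.591,0.302,11
Leptogorgia sarmentosa,Detrital littoral sandy mud,deep,0.057,0.193,211,0.600,0.262,20
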