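measure,n2o_reduction_pct,energy_reduction_pct,biodiversity_score
Management of in-field ponds,-10,,5
Uncropped cultivated areas,-10,-10,5
Undersown spring cereals,-50,-50,2.5
"Cultivate land for crops in spring, retaining over-winter stubbles",-10,,2.5
Establish and maintain artificial wetlands-steading runoff,-25,,1
Use clover in place of fertilizer nitrogen,-10,-40,1
Establish cover crops in the autumn,-50,75,0.2
Early harvesting and establishment of crops in the autumn,-25,,0.2
Adopt reduced cultivation systems,-10,-50 to 25,0.2
Leave residual levels of non-aggressive weeds in crops,-10,,2.5
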