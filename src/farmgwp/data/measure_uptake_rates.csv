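measure,uptake_rate
"Adopt phase feeding of livestock: dairy, pigs",80
Allow cattle slurry stores to develop a natural crust,80
Construct bridges for livestock crossing rivers/streams,80
Reduce field stocking rates when soils are wet,80
Early harvesting and establishment of crops in the autumn,50
Loosen compacted soil layers in grassland fields,50
Move feeders at regular intervals,50
Cultivate and drill across the slope,25
Re-site gateways away from high-risk areas,25
Washing down of dairy cow collecting yards,25
Additional targeted bedding for straw-bedded cattle housing,10
Establish in-field grass buffer strips,10
Extend the grazing season for cattle,10
Improved livestock through breeding,10
Increase scraping frequency in dairy cow cubicle housing,10
In-house poultry manure drying,10
Install covers to slurry stores,10
Locate out-wintered stock away from watercourses,10
Reduce the length of the grazing day/grazing season,10
Use clover in place of fertilizer nitrogen,10
Use high-sugar grasses,10
Use manufactured fertilizer placement technologies,10
Beetle banks,2
Compost solid manure,2
Construct troughs with concrete base,2
Cover solid manure stores with sheeting,2
Establish new hedges,2
Frequent removal of slurry from beneath-slat storage in pig housing,2
Leave residual levels of non-aggressive weeds in crops,2
Management of arable field corners,2
Management of grassland field corners,2
Management of in-field ponds,2
Management of woodland edges,2
Plant areas of the farm with wild bird seed/nectar flower mixtures,2
Skylark plots,2
Uncropped cultivated areas,2
Uncropped cultivated margins,2
Undersown spring cereals,2
Unfertilised cereal headlands,2
Unharvested cereal headlands,2
Use liquid/solid manure separation techniques,2
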