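# SYNTHETIC implementer-supplied defaults. Applicability and per-pollutant
# efficacies (signed %, negative = reduction) for measures whose effects are
# not printed in the transcribed catalogue tables. Editable; not survey values.
measure,applicable_farm_types,eff_ch4,eff_nitrate,eff_phosphorus,eff_sediment,uptake_min,uptake_max
"Cultivate land for crops in spring rather than autumn, retaining over-winter stubbles",cereals;general_cropping;horticulture;mixed,,-15,-20,-30,,
"Reduce dietary N and P intakes: dairy, pigs, poultry",dairy;pigs;poultry,-5,-8,-10,,,
Do not apply manufactured fertilizer to high-risk areas,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-10,-5,,,
Fertilizer spreader calibration,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-5,-2,,,
Integrate fertilizer and manure nutrient supply,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-10,,,,
Do not apply manure to high-risk areas,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-8,-10,-2,,
Site solid manure heaps away from watercourses/field drains,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-3,-5,,,
Use a fertilizer recommendation system,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-12,-3,,,
Adopt reduced cultivation systems,cereals;general_cropping;horticulture;mixed,,,-30,-40,,
Manure spreader calibration,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-4,-2,,,
Capture of dirty water in a dirty water store,dairy,,-3,-8,,,
"Treatment of PPP washings through disposal, activated carbon, or biobeds",cereals;general_cropping;horticulture;mixed,,,,,,
Cultivate compacted tillage soils,cereals;general_cropping;horticulture;mixed,,,-10,-15,,
Farm track management,lowland_grazing;lfa_grazing;dairy;mixed,,,-5,-10,,
Fence off rivers and streams from livestock,lowland_grazing;lfa_grazing;dairy;mixed,,-2,-8,-10,,
Use correctly inflated low-ground pressure tires on machinery,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,,,-5,,
Establish cover crops in the autumn,cereals;general_cropping;horticulture;mixed,,-40,-15,-25,,
Establish riparian buffer strips,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-5,-25,-30,,
Incorporate manure into the soil,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,,-5,,,
Leave autumn seedbeds rough,cereals;general_cropping;horticulture;mixed,,,-15,-20,,
Manage over-winter tramlines,cereals;general_cropping;horticulture;mixed,,,-20,-25,,
Minimize the volume of dirty water produced,dairy,,-2,-5,,,
Ditch management,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-3,-8,-10,,
Use slurry band spreading application techniques,lowland_grazing;dairy;mixed;pigs,,,,,,
"Adopt phase feeding of livestock: dairy, pigs",dairy;pigs,-5,-5,,,,
Allow cattle slurry stores to develop a natural crust,lowland_grazing;lfa_grazing;dairy;mixed,-5,,,,,
Construct bridges for livestock crossing rivers/streams,lowland_grazing;lfa_grazing;dairy;mixed,,,-5,-8,,
Reduce field stocking rates when soils are wet,lowland_grazing;lfa_grazing;dairy;mixed,,,-8,-10,,
Early harvesting and establishment of crops in the autumn,cereals;general_cropping;horticulture;mixed,,,,-10,,
Loosen compacted soil layers in grassland fields,lowland_grazing;lfa_grazing;dairy;mixed,,,-5,-5,,
Move feeders at regular intervals,lowland_grazing;lfa_grazing;dairy;mixed,,,-5,-5,,
Cultivate and drill across the slope,cereals;general_cropping;horticulture;mixed,,,-15,-20,,
Re-site gateways away from high-risk areas,lowland_grazing;lfa_grazing;dairy;mixed,,,-8,-10,,
Washing down of dairy cow collecting yards,dairy,,-1,-3,,,
Additional targeted bedding for straw-bedded cattle housing,lowland_grazing;lfa_grazing;dairy;mixed,-2,,,,,
Establish in-field grass buffer strips,cereals;general_cropping;horticulture;mixed,,-3,-10,-15,,
Extend the grazing season for cattle,lowland_grazing;lfa_grazing;dairy;mixed,-3,5,3,5,,
Improved livestock through breeding,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,-10,,,,,
Increase scraping frequency in dairy cow cubicle housing,dairy,-2,,,,,
In-house poultry manure drying,poultry,-5,,,,,
Install covers to slurry stores,lowland_grazing;dairy;mixed;pigs,-10,,,,,
Locate out-wintered stock away from watercourses,lowland_grazing;lfa_grazing;dairy;mixed,,-2,-8,-10,,
Reduce the length of the grazing day/grazing season,lowland_grazing;lfa_grazing;dairy;mixed,2,,-5,-8,,
Use clover in place of fertilizer nitrogen,lowland_grazing;lfa_grazing;dairy;mixed,,-5,,,,
Use high-sugar grasses,lowland_grazing;lfa_grazing;dairy;mixed,-5,-3,,,,
Use manufactured fertilizer placement technologies,cereals;general_cropping;horticulture;mixed,,-5,,,,
Beetle banks,cereals;general_cropping;horticulture;mixed,,,-3,-5,,
Compost solid manure,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,-5,,,,,
Construct troughs with concrete base,lowland_grazing;lfa_grazing;dairy;mixed,,,-2,-3,,
Cover solid manure stores with sheeting,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,-3,-2,,,,
Establish new hedges,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,,-3,-5,,
Frequent removal of slurry from beneath-slat storage in pig housing,pigs,-10,,,,,
Leave residual levels of non-aggressive weeds in crops,cereals;general_cropping;horticulture;mixed,,,,-3,,
Management of arable field corners,cereals;general_cropping;horticulture;mixed,,-2,-3,-5,,
Management of grassland field corners,lowland_grazing;lfa_grazing;dairy;mixed,,,-2,-3,,
Management of in-field ponds,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,,-5,-8,,
Management of woodland edges,cereals;general_cropping;horticulture;lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,,,-2,,
Plant areas of the farm with wild bird seed/nectar flower mixtures,cereals;general_cropping;horticulture;mixed,,-2,,-3,,
Skylark plots,cereals,,,,-1,,
Uncropped cultivated areas,cereals;general_cropping;horticulture;mixed,,-3,,-5,,
Uncropped cultivated margins,cereals;general_cropping;horticulture;mixed,,-2,-3,-5,,
Undersown spring cereals,cereals;mixed,,-15,,-10,,
Unfertilised cereal headlands,cereals;mixed,,-5,,,,
Unharvested cereal headlands,cereals;mixed,,-2,,,,
Use liquid/solid manure separation techniques,dairy;pigs,-8,,,,,
Establish and maintain artificial wetlands-steading runoff,lowland_grazing;lfa_grazing;dairy;mixed;pigs;poultry,,-5,-10,-5,2,2
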