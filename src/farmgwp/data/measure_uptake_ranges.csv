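measure,uptake_min,uptake_max
"Cultivate land for crops in spring rather than autumn, retaining over-winter stubbles",2,80
"Reduce dietary N and P intakes: dairy, pigs, poultry",10,80
Do not apply manufactured fertilizer to high-risk areas,25,80
Fertilizer spreader calibration,25,80
Integrate fertilizer and manure nutrient supply,25,80
Do not apply manure to high-risk areas,50,100
Site solid manure heaps away from watercourses/field drains,50,100
Use a fertilizer recommendation system,50,100
Adopt reduced cultivation systems,2,50
Manure spreader calibration,10,50
Capture of dirty water in a dirty water store,50,80
"Treatment of PPP washings through disposal, activated carbon, or biobeds",50,80
Cultivate compacted tillage soils,25,50
Farm track management,25,50
Fence off rivers and streams from livestock,25,50
Use correctly inflated low-ground pressure tires on machinery,25,50
Establish cover crops in the autumn,2,25
Establish riparian buffer strips,10,25
Incorporate manure into the soil,10,25
Leave autumn seedbeds rough,10,25
Manage over-winter tramlines,10,25
Minimize the volume of dirty water produced,10,25
Ditch management,0,50
Use slurry band spreading application techniques,2,10
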