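cause_id,name,level,parent_id,fatal_estimated,nonfatal_estimated,excluded_age_groups,icd9_codes,icd10_codes
all_injuries,All injuries,0,,1,1,,,
transport,Transport injuries,1,all_injuries,1,1,,,
unintentional,Unintentional injuries,1,all_injuries,1,1,,,
self_harm_violence,Self-harm and interpersonal violence,1,all_injuries,1,1,,,
forces_conflict_exec,"Forces of nature, conflict and terrorism and executions and police conflict",1,all_injuries,1,1,,,
road,Road injuries,2,transport,1,1,,"E800.3-E829.4","V01-V04.99; V06-V80.929; V82-V82.9; V87.2-V87.3"
pedestrian_road,Pedestrian road injuries,3,road,1,1,,"E811.7-E829.0","V01-V04.99; V06-V09.9"
cyclist_road,Cyclist road injuries,3,road,1,1,,"E800.3-E826.1","V10-V19.9"
motorcyclist_road,Motorcyclist road injuries,3,road,1,1,,"E810.2-E825.3","V20-V29.9"
motor_vehicle_road,Motor vehicle road injuries,3,road,1,1,,"E810.0-E825.1","V30-V79.9; V87.2-V87.3"
other_road,Other road injuries,3,road,1,1,,"E810.4-E829.4","V80-V80.929; V82-V82.9"
other_transport,Other transport injuries,2,transport,1,1,,"E800-E849.9; E929.1","V00-V00.898; V05-V05.99; V81-V81.9; V83-V86.99; V88.2-V88.3; V90-V98.8"
falls,Falls,2,unintentional,1,1,,"E880-E886.99; E888-E888.9; E929.3","W00-W19.9"
drowning,Drowning,2,unintentional,1,1,,"E910-E910.99","W65-W70.9; W73-W74.9"
fire_heat,"Fire, heat and hot substances",2,unintentional,1,1,,"E890-E899.09; E924-E924.99; E929.4","X00-X06.9; X08-X19.9"
poisonings,Poisonings,2,unintentional,1,1,,"E850.3-E858.99; E862-E869.99; E929.2","J70.5; X40-X44.9; X47-X49.9; Y10-Y14.9; Y16-Y19.9"
poisoning_co,Poisoning by carbon monoxide,3,poisonings,1,1,,"E862-E862.99; E868-E869.99","J70.5; X47-X47.9"
poisoning_other,Poisoning by other means,3,poisonings,1,1,,"E850.3-E858.99; E866-E866.99","X40-X44.9; X49-X49.9; Y10-Y14.9; Y16-Y19.9"
mechanical_forces,Exposure to mechanical forces,2,unintentional,1,1,,"E913-E913.19; E916-E922.99; E928.1-E928.7","W20-W38.9; W40-W43.9; W45.0-W45.2; W46-W46.2; W49-W52; W75-W76.9"
unintentional_firearm,Unintentional firearm injuries,3,mechanical_forces,1,1,,"E922-E922.99; E928.7","W32-W34.9"
unintentional_suffocation,Unintentional suffocation,3,mechanical_forces,1,1,,,"W75-W76.9"
other_mechanical,Other exposure to mechanical forces,3,mechanical_forces,1,1,,"E916-E921.99; E928.1-E928.6","W20-W31.9; W35-W38.9; W40-W43.9; W45.0-W45.2; W46-W46.2; W49-W52"
adverse_medical,Adverse effects of medical treatment,2,unintentional,1,1,,,
animal_contact,Animal contact,2,unintentional,1,1,,"E905-E906.99","W52.0-W62.9; W64-W64.9; X20-X29.9"
venomous_animal,Venomous animal contact,3,animal_contact,1,1,,"E905-E905.99","W52.3; X20-X29.9"
nonvenomous_animal,Non-venomous animal contact,3,animal_contact,1,1,,"E905-E906.99","W52.0-W62.9; W64-W64.9"
foreign_body,Foreign body,2,unintentional,1,1,,,
fb_airway,Pulmonary aspiration and foreign body in airway,3,foreign_body,1,1,,"770.1-770.18; E911-E912.09; E913.8-E913.99","W78-W80.9; W83-W84.9"
fb_eyes,Foreign body in eyes,3,foreign_body,0,1,,"360.5-360.69; 374.86; 376.6; E914-E914.09","H02.81-H02.819; H44.6-H44.799"
fb_other,Foreign body in other body part,3,foreign_body,1,1,,"709.4; E915-E915.09","M60.2-M60.28; W44-W45; W45.3-W45.9"
environmental_heat_cold,Environmental heat and cold exposure,2,unintentional,1,1,,,
other_unintentional,Other unintentional injuries,2,unintentional,1,1,,,
self_harm,Self-harm,2,self_harm_violence,1,1,enn,"E950-E959","X60-X64.9; X66-X84.9; Y87.0"
self_harm_firearm,Self-harm by firearm,3,self_harm,1,1,enn,"E955-E955.9","X72-X74.9"
self_harm_other,Self-harm by other specified means,3,self_harm,1,1,enn,"E950-E954; E956-E958.0; E958.2-E959","X60-X64.9; X66-X67.9; X69-X71.9; X75-X75.9; X77-X84.9; Y87.0"
interpersonal_violence,Interpersonal violence,2,self_harm_violence,1,1,,"E960-E969","X85-Y08.9; Y87.1-Y87.2"
assault_firearm,Physical violence by firearm,3,interpersonal_violence,1,1,,"E965-E965.4","X93-X95.9"
assault_sharp,Physical violence by sharp object,3,interpersonal_violence,1,1,,"E966","X99-X99.9"
assault_other,Physical violence by other means,3,interpersonal_violence,1,1,,"E961-E964; E965.5-E965.9; E967-E969","X85-X92.9; X96-X98.9; Y00-Y04.9; Y06-Y08.9; Y87.1-Y87.2"
sexual_violence,Sexual violence,3,interpersonal_violence,0,1,,"E960-E960.1","Y05-Y05.9"
forces_of_nature,Exposure to forces of nature,2,forces_conflict_exec,1,1,,"E907-E909.9","X33-X38.9"
conflict_terrorism,Conflict and terrorism,2,forces_conflict_exec,1,1,,"E979-E979.9; E990-E999.1","U00-U03; Y36-Y38.9; Y89.1"
executions_police,Executions and police conflict,2,forces_conflict_exec,1,1,,"E970-E978","Y35-Y35.93; Y89.0"
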