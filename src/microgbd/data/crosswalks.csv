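cause_id,category,ratio,lower,upper
animal_contact,outpatient,7.04,7.03,7.04
animal_contact,formal_care,7.56,6.91,8.31
nonvenomous_animal,outpatient,2.91,2.91,2.92
nonvenomous_animal,formal_care,11.21,10.1,12.38
venomous_animal,outpatient,3.14,3.01,3.34
venomous_animal,formal_care,4.09,3.69,4.5
drowning,outpatient,0.88,0.87,0.89
drowning,formal_care,1.01,1.0,1.05
drowning,warranted_care,30.42,15.33,51.11
falls,outpatient,6.91,6.89,6.94
falls,formal_care,5.94,5.5,6.46
falls,warranted_care,9.73,9.28,10.22
fire_heat,outpatient,3.53,3.53,3.56
fire_heat,formal_care,7.82,7.24,8.51
fb_airway,outpatient,3.37,3.35,3.43
fb_airway,formal_care,15.36,13.93,16.86
fb_eyes,outpatient,931.4,923.34,934.49
fb_eyes,formal_care,302.06,251.14,365.04
fb_other,outpatient,1.97,1.95,2.01
fb_other,formal_care,20.97,15.55,26.26
interpersonal_violence,outpatient,6.57,6.56,6.61
interpersonal_violence,formal_care,21.43,13.6,32.79
interpersonal_violence,warranted_care,46.97,39.57,53.62
assault_firearm,outpatient,1.36,1.29,1.44
assault_firearm,formal_care,1.27,1.05,1.6
assault_firearm,warranted_care,53.58,50.65,54.54
assault_sharp,outpatient,3.18,2.92,3.5
assault_sharp,formal_care,2.38,1.86,3.22
assault_sharp,warranted_care,37.91,28.3,50.05
assault_other,outpatient,5.65,5.44,5.89
assault_other,formal_care,2.44,2.02,3.2
mechanical_forces,outpatient,12.4,12.0,12.82
mechanical_forces,formal_care,33.3,30.51,36.23
unintentional_firearm,outpatient,2.71,2.53,2.9
unintentional_firearm,formal_care,4.6,3.49,6.36
other_mechanical,outpatient,12.62,12.55,12.85
other_mechanical,formal_care,30.77,25.74,36.09
adverse_medical,outpatient,1.06,1.06,1.06
adverse_medical,formal_care,19.81,17.29,26.1
environmental_heat_cold,outpatient,3.91,3.9,3.94
environmental_heat_cold,warranted_care,17.54,3.91,49.6
other_unintentional,outpatient,13.53,13.46,13.78
other_unintentional,warranted_care,14.95,9.62,24.12
poisonings,outpatient,3.96,3.73,4.19
poisonings,formal_care,3.78,3.4,4.21
poisonings,warranted_care,8.47,4.41,16.64
poisoning_co,outpatient,5.86,5.68,5.92
poisoning_other,outpatient,4.18,3.9,4.5
self_harm,outpatient,2.75,2.75,2.78
self_harm,formal_care,2.5,2.2,2.83
self_harm_firearm,outpatient,2.77,2.42,3.07
self_harm_firearm,formal_care,16.94,2.81,51.06
self_harm_other,outpatient,1.5,1.47,1.51
self_harm_other,formal_care,6.73,2.78,19.14
other_transport,outpatient,1.65,1.6,1.77
other_transport,formal_care,1.01,1.0,1.03
road,outpatient,3.77,3.75,3.78
road,formal_care,6.16,5.65,6.68
road,warranted_care,15.44,13.25,18.1
motorcyclist_road,outpatient,1.94,1.92,1.99
motor_vehicle_road,outpatient,4.48,4.46,4.48
other_road,outpatient,6.9,6.89,6.96
cyclist_road,outpatient,4.54,4.33,4.89
pedestrian_road,outpatient,1.94,1.94,1.96
pedestrian_road,formal_care,15.78,7.63,36.6
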