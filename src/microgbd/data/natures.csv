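nature_id,name,dw_short,dw_long,long_term_only,no_long_term,p_long_default
amp_lower_bilateral,"Amputation of lower limbs, bilateral",,0.4430,1,0,1.0
amp_upper_bilateral,"Amputation of upper limbs, bilateral",,0.3590,1,0,1.0
amp_fingers,Amputation of fingers (excluding thumb),,0.0300,1,0,1.0
amp_lower_unilateral,"Amputation of lower limb, unilateral",,0.1730,1,0,1.0
amp_upper_unilateral,"Amputation of upper limb, unilateral",,0.1180,1,0,1.0
amp_thumb,Amputation of thumb,,0.0110,1,0,1.0
amp_toes,Amputation of toe/toes,,0.0080,1,0,1.0
burns_airway,Lower airway burns,0.3764,0.3764,0,0,0.5
burns_lt20,"Burns, <20% total burned surface area without lower airway burns",0.1408,0.1408,0,0,0.5
burns_ge20,"Burns, >=20% total burned surface area or >=10% burned surface area if head/neck or hands/wrist involved without lower airway burns",0.3145,0.3145,0,0,0.5
fx_clavicle,"Fracture of clavicle, scapula or humerus",0.0349,0.0349,0,0,0.5
fx_face,Fracture of face bones,0.0669,0.0669,0,0,0.5
fx_foot,Fracture of foot bones except ankle,0.0260,0.0260,0,0,0.5
fx_hand,Fracture of hand (wrist and other distal part of hand),0.0099,0.0099,0,0,0.5
fx_hip,Fracture of hip,0.2575,0.2575,0,0,0.5
fx_patella_tibia,"Fracture of patella, tibia or fibula or ankle",0.0501,0.0501,0,0,0.5
fx_pelvis,Fracture of pelvis,0.2788,0.2788,0,0,0.5
fx_radius_ulna,Fracture of radius and/or ulna,0.0281,0.0281,0,0,0.5
fx_skull,Fracture of skull,0.0714,0.0714,0,0,0.5
fx_sternum_ribs,Fracture of sternum and/or fracture of one or more ribs,0.1027,0.1027,0,0,0.5
fx_vertebral,Fracture of vertebral column,0.1106,0.1106,0,0,0.5
fx_femur,"Fracture of femur, other than femoral neck",0.1114,0.1114,0,0,0.5
tbi_minor,Minor TBI,0.1100,0.1100,0,0,0.5
tbi_mod_severe,Moderate/severe TBI,0.2137,0.2137,0,0,0.5
sci_neck,Spinal cord lesion at neck level,0.7319,0.7319,0,0,0.5
sci_below_neck,Spinal cord lesion below neck level,0.6235,0.6235,0,0,0.5
muscle_tendon,"Muscle and tendon injuries, including sprains and strains lesser dislocations",0.0075,0.0075,0,0,0.5
fb_ear,Foreign body in ear,0.0133,,0,1,0.0
open_wound,Open wound(s),0.0058,0.0058,0,0,0.5
contusion,Contusion in any part of the body,0.0075,0.0075,0,0,0.5
superficial,Superficial injury of any part of the body,0.0075,,0,1,0.0
disloc_hip,Dislocation of hip,0.0159,0.0159,0,0,0.5
disloc_knee,Dislocation of knee,0.1134,0.1134,0,0,0.5
disloc_shoulder,Dislocation of shoulder,0.0620,0.0620,0,0,0.5
fb_respiratory,Foreign body in respiratory system,0.4079,,0,1,0.0
fb_gi_urogenital,Foreign body in GI and urogenital system,0.1143,,0,1,0.0
drowning_submersion,Drowning and non-fatal submersion,0.2471,0.2471,0,0,0.5
asphyxiation,Asphyxiation,0.2471,0.2471,0,0,0.5
crush,Crush injury,0.1325,0.1325,0,0,0.5
nerve,Nerve injury,0.0997,0.0997,0,0,0.5
eye_injury,Injury to eyes,0.0543,0.0543,0,0,0.5
poisoning_urgent,Poisoning requiring urgent care,0.1628,0.1628,0,0,0.5
chest_severe,Severe chest injury,0.3685,0.3685,0,0,0.5
internal_haemorrhage,Internal haemorrhage in abdomen and pelvis,0.3242,0.3242,0,0,0.5
env_factors,Effect of different environmental factors,0.1334,0.1334,0,0,0.5
therapeutic_complications,Complications following therapeutic procedures,0.1334,0.1334,0,0,0.5
multiple_injuries,"Multiple fractures, dislocations, crashes, wounds, pains and strains",0.2575,0.2575,0,0,0.5
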