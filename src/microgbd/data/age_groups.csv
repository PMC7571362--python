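age_group_id,name,age_start,age_end
enn,Early neonatal (0-6 days),0.0,0.01917808
lnn,Late neonatal (7-27 days),0.01917808,0.07671233
pnn,Post neonatal (28-364 days),0.07671233,1.0
1-4,1 to 4,1.0,5.0
5-9,5 to 9,5.0,10.0
10-14,10 to 14,10.0,15.0
15-19,15 to 19,15.0,20.0
20-24,20 to 24,20.0,25.0
25-29,25 to 29,25.0,30.0
30-34,30 to 34,30.0,35.0
35-39,35 to 39,35.0,40.0
40-44,40 to 44,40.0,45.0
45-49,45 to 49,45.0,50.0
50-54,50 to 54,50.0,55.0
55-59,55 to 59,55.0,60.0
60-64,60 to 64,60.0,65.0
65-69,65 to 69,65.0,70.0
70-74,70 to 74,70.0,75.0
75-79,75 to 79,75.0,80.0
80-84,80 to 84,80.0,85.0
85-89,85 to 89,85.0,90.0
90-94,90 to 94,90.0,95.0
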