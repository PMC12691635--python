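patient_id,sex,age_years,joint,isolates,polymicrobial,prior_iv_agent,prior_iv_days,gfr_ml_min,albumin_g_l,second_stage_surgery,second_stage_culture_positive,surgery_interval_days,followup_days
P01,female,62,hip,Cutibacterium acnes,False,vancomycin,8,62.0,33,True,True,70.0,520.0
P02,female,65,hip,Staphylococcus epidermidis;Cutibacterium acnes,True,vancomycin,9,68.0,35,True,False,76.0,560.0
P03,female,67,hip,Staphylococcus epidermidis;Cutibacterium acnes,True,vancomycin,9,71.0,36,True,False,80.0,600.0
P04,female,68,hip,Staphylococcus epidermidis;Cutibacterium acnes,True,vancomycin,10,74.0,37,True,False,85.0,630.0
P05,female,69,hip,Staphylococcus capitis;Cutibacterium acnes,True,vancomycin,10,75.8,38,True,False,85.0,630.0
P06,female,69,hip,Staphylococcus epidermidis,False,vancomycin,10,75.8,38,True,False,85.0,630.0
P07,female,71,hip,Staphylococcus epidermidis,False,vancomycin,10,80.0,40,True,False,100.0,662.0
P08,female,72,hip,Staphylococcus epidermidis,False,vancomycin,11,84.0,42,True,False,112.0,680.0
P09,female,74,hip,Staphylococcus epidermidis,False,vancomycin,11,88.0,44,True,False,125.0,685.0
P10,female,75,hip,Staphylococcus epidermidis,False,vancomycin,11,89.0,44,True,False,134.0,693.0
P11,female,76,hip,Staphylococcus epidermidis,False,vancomycin,12,91.0,46,True,False,140.0,720.0
P12,female,77,knee,Staphylococcus epidermidis,False,vancomycin,12,93.0,46,True,False,152.0,760.0
P13,female,78,knee,Staphylococcus epidermidis,False,vancomycin,13,94.0,46,True,False,160.0,800.0
P14,female,78,knee,Staphylococcus epidermidis,False,vancomycin,14,95.0,46,True,False,175.0,824.0
P15,male,79,knee,Staphylococcus lugdunensis,False,vancomycin,16,96.3,47,True,False,175.0,824.0
P16,male,79,knee,Staphylococcus capitis,False,daptomycin,16,96.3,47,True,False,190.0,860.0
P17,male,81,knee,Staphylococcus hominis,False,daptomycin,17,98.0,48,True,False,220.0,910.0
P18,male,83,shoulder,Staphylococcus pettenkoferi,False,daptomycin,18,101.0,49,True,False,260.0,980.0
P19,male,85,shoulder,Cutibacterium acnes,False,daptomycin,20,104.0,50,True,False,300.0,1040.0
P20,male,88,ankle,Enterococcus faecalis,False,daptomycin,22,108.0,51,False,,,
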