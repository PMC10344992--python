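resource,state,unit_cost,annual_use,fraction
General practitioner,pre_ataxic,37.00,1.5,1.00
Neurologist,pre_ataxic,110.00,0.5,1.00
Medication,slight,2.41,365,0.33
General practitioner,slight,37.00,1.5,1.00
Occupational physician,slight,28.00,1.5,1.00
Physical therapy,slight,37.00,39,1.00
Neurologist,slight,110.00,1,1.00
Rehabilitation physician,slight,101.00,1,1.00
Medication,moderate,2.41,365,0.33
General practitioner,moderate,37.00,1.5,1.00
Occupational physician,moderate,28.00,1.5,1.00
Physical therapy,moderate,37.00,52,1.00
Speech therapy,moderate,33.00,9,1.00
Occupational therapy,moderate,37.00,1.5,0.50
Neurologist,moderate,110.00,1,1.00
Rehabilitation physician,moderate,101.00,1,1.00
Partner/family/friends,moderate,15.50,390,0.33
Home care,moderate,77.50,312.5,0.20
Medication,severe,2.41,365,0.33
General practitioner,severe,37.00,1.5,1.00
Physical therapy,severe,37.00,78,1.00
Speech therapy,severe,33.00,9,1.00
Occupational therapy,severe,37.00,1.5,0.50
Neurologist,severe,110.00,1,1.00
Rehabilitation physician,severe,101.00,1,1.00
Partner/family/friends,severe,15.50,806,0.75
Home care,severe,77.50,312.5,0.80
Nursing home care,severe,186.00,365,0.10
Medication,end_stage,2.41,365,0.33
General practitioner,end_stage,37.00,1.5,1.00
Partner/family/friends,end_stage,15.50,1558,0.10
Home care,end_stage,77.50,312.5,0.10
Nursing home care,end_stage,186.00,365,0.90
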