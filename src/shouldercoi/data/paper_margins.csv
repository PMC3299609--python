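group,n,component,mean_units,sd_units,total_units,cost_mean,cost_sd,total_cost
full,204,gp,0.89,0.97,181,95,105,19429
full,204,pt,3.91,7.40,798,195,369,39825
full,204,xray,0.28,0.45,57,18,29,3719
full,204,ultrasound,0.11,0.31,23,14,39,2857
full,204,medicine,0.28,,58,4,6,718
full,204,healthcare_total,,,,326,389,66548
full,204,sick_leave,9.04,29.17,1844,1743,5626,355610
full,204,total,,,,2069,5730,422158
high_cost,45,gp,1.71,1.42,77,184,153,8266
high_cost,45,pt,8.20,13.62,369,409,680,18415
high_cost,45,xray,0.33,,15,22,31,979
high_cost,45,ultrasound,0.27,,12,33,56,1490
high_cost,45,medicine,0.47,,21,6,7,262
high_cost,45,healthcare_total,,,,654,671,29412
high_cost,45,sick_leave,40.82,50.98,1837,7875,9833,354356
high_cost,45,total,,,,8528,9829,383768
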