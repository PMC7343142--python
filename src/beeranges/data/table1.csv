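bee_id,stage,n_waypoints,start_date,end_date,n_days,nest,nest_substrate,mcp_ha,max_homing_m
oo5,before_nest,8,2015-07-30,2015-08-04,6,no,,93.1,1573.5
o85,before_nest,30,2015-08-02,2015-08-07,6,no,,11.2,593.82
105,before_nest,20,2015-07-29,2015-08-06,9,no,,20.9,870.58
124,before_nest,41,2015-07-28,2015-08-05,9,no,,2.84,296.18
144,before_nest,32,2015-07-30,2015-08-07,9,no,,17.4,1088.02
304,before_nest,17,2015-07-28,2015-08-01,5,no,,7.46,766.11
304.2,before_nest,18,2015-08-05,2015-08-07,3,no,,6.1,508.52
164,after_nest,38,2015-09-17,2015-09-22,6,yes,Blueberry,0.96,187.4
185.3,after_nest,65,2015-09-16,2015-09-22,7,yes,Casuarina sp. windbreaks,13.5,1167.29
244,after_nest,15,2015-09-02,2015-09-07,5,yes,Eucalyptus plantation,7.88,771.56
244.2,after_nest,18,2015-09-09,2015-09-10,2,yes,Savanna,0.55,256.77
244.3,after_nest,7,2015-09-10,2015-09-11,2,yes,Eucalyptus plantation,0.95,853.13
264,after_nest,46,2015-09-16,2015-09-22,7,yes,Young Eucalyptus plantation,2.68,277.03
264.1,after_nest,11,2015-09-16,2015-09-16,1,yes,Young Eucalyptus plantation,5.13,827.42
364.2,after_nest,20,2015-09-19,2015-09-19,1,no,,0.96,289.18
364,after_nest,34,2015-08-31,2015-09-01,2,yes,Citrus,1.56,184.15
385,after_nest,53,2015-09-18,2015-09-22,5,yes,Old Blueberry,1.35,413.19
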