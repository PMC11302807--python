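modality,resource,stage,cost_usd
CTgRT,therapist,simulation,255.60
CTgRT,therapist,treatment,340.80
CTgRT,cma,consultation,4.80
CTgRT,cma,on-treatment visit,4.80
CTgRT,cma,follow-up,4.80
CTgRT,nurse,consultation,22.40
CTgRT,nurse,simulation,2.56
CTgRT,nurse,on-treatment visit,9.60
CTgRT,nurse,follow-up,12.80
CTgRT,physicist,simulation,278.46
CTgRT,physicist,planning,163.80
CTgRT,physicist,treatment,489.06
CTgRT,attending,consultation,341.00
CTgRT,attending,simulation,44.00
CTgRT,attending,planning,154.00
CTgRT,attending,treatment,176.00
CTgRT,attending,on-treatment visit,57.20
CTgRT,attending,follow-up,132.00
CTgRT,dosimetrist,planning,242.82
CTgRT,resident,planning,33.63
MRgRT,therapist,consultation,14.20
MRgRT,therapist,simulation,149.81
MRgRT,therapist,treatment,1150.20
MRgRT,cma,consultation,4.80
MRgRT,cma,on-treatment visit,4.80
MRgRT,cma,follow-up,4.80
MRgRT,nurse,consultation,22.40
MRgRT,nurse,on-treatment visit,9.60
MRgRT,nurse,follow-up,12.80
MRgRT,physicist,simulation,29.25
MRgRT,physicist,planning,124.02
MRgRT,physicist,treatment,1053.00
MRgRT,attending,consultation,385.00
MRgRT,attending,simulation,57.20
MRgRT,attending,planning,154.00
MRgRT,attending,treatment,550.00
MRgRT,attending,on-treatment visit,57.20
MRgRT,attending,follow-up,132.00
MRgRT,dosimetrist,simulation,22.80
MRgRT,dosimetrist,planning,222.30
MRgRT,dosimetrist,treatment,456.00
MRgRT,resident,planning,61.95
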