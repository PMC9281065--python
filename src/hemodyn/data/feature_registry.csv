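variable,category,units,lo,hi,staleness_h,fallback,ref_value,ref_sd
heart_rate,vital,bpm,20,300,4,none,86,15
sbp_invasive,vital,mmHg,30,300,4,nibp_to_ibp,122,22
dbp_invasive,vital,mmHg,10,200,4,nibp_to_ibp,64,13
map_invasive,vital,mmHg,20,250,4,nibp_to_ibp,83,15
sbp_noninvasive,vital,mmHg,30,300,4,none,120,20
dbp_noninvasive,vital,mmHg,10,200,4,none,65,12
map_noninvasive,vital,mmHg,20,250,4,none,84,14
resp_rate,vital,breaths/min,4,60,4,none,18,5
spo2,vital,%,50,100,4,none,97,2.5
temperature,vital,degC,30,43,4,none,36.8,0.7
cvp,vital,mmHg,-5,50,4,none,9,4
glucose,lab,mg/dL,20,1000,48,none,140,45
bun,lab,mg/dL,1,200,48,none,24,12
creatinine,lab,mg/dL,0.1,20,48,none,1.3,0.8
ast,lab,U/L,1,5000,48,none,45,30
alt,lab,U/L,1,5000,48,none,38,25
bilirubin_total,lab,mg/dL,0.1,60,48,none,1.1,0.9
hemoglobin,lab,g/dL,2,25,48,none,10.8,1.9
hematocrit,lab,%,10,70,48,none,32,5.5
platelets,lab,10^3/uL,1,1500,48,none,180,75
wbc,lab,10^3/uL,0.1,200,48,none,11,4.5
sodium,lab,mmol/L,110,180,48,none,139,4.5
potassium,lab,mmol/L,1,9,48,none,4.0,0.5
ph,blood_gas,pH,6.8,7.8,48,none,7.38,0.06
pao2,blood_gas,mmHg,30,600,48,none,95,25
paco2,blood_gas,mmHg,10,150,48,none,40,7
bicarbonate,blood_gas,mmol/L,5,50,48,none,23,4
lactate,blood_gas,mmol/L,0.1,30,48,none,1.8,1.0
fio2,ventilation,fraction,0.21,1.0,8,fio2_room_air,0.4,0.12
peak_airway_pressure,ventilation,cmH2O,1,80,8,none,22,5
mean_airway_pressure,ventilation,cmH2O,1,50,8,none,11,3
peep,ventilation,cmH2O,0,30,8,none,6,2
tidal_volume,ventilation,mL,50,2000,8,none,450,80
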