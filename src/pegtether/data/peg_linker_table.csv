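name,mw_da,n_units,contour_length_nm,flory_radius_nm,fret_efficiency_pct
PEG 88,88,2,0.6,0.5,58
PEG 484,484,11,3.1,1.2,53
PEG 2000,2000,45,12.7,2.8,34
PEG 3500,3500,80,22.3,3.9,20
PEG 5000,5000,114,31.8,4.8,14
PEG 7500,7500,170,47.7,6.1,2
PEG 15000,15000,341,95.5,9.3,
PEG 30000,30000,682,190.9,14.0,
PEG 60000,60000,1364,381.8,21.3,
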