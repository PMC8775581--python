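# id: Lu-177
# half_life_days: 6.647
# beta_file: lu177_beta.csv
component,energy_keV,yield
auger,0.12,0.6
auger,0.95,0.4
auger,1.7,0.15
auger,5.6,0.06
auger,6.6,0.04
auger,43.0,0.003
ic,110.0,0.12
xray,2.5,0.15
gamma,172.0,0.166
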