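nuclide,energy_kev,emission_probability,series
Pb-214,295.2,0.184,U-238
Pb-214,351.93,0.356,U-238
Bi-214,609.31,0.455,U-238
Bi-214,1764.49,0.153,U-238
Pb-212,238.63,0.433,Th-232
Tl-208,583.19,0.304,Th-232
Ac-228,911.21,0.258,Th-232
Tl-208,2614.53,0.356,Th-232
K-40,1460.83,0.1066,K-40
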