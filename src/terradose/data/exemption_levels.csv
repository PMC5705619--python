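radionuclide,bq_per_g,pci_per_g,default_screen
Ra-226,1.1,30,1
Ra-228,1.1,30,1
Pb-210,0.2,5,1
Po-210,0.2,5,1
Pb-238 (as printed),5.5,150,0
U(nat),3.0,80,1
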