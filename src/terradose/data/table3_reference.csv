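sample_id,ra_eq,elcr,elcr_sd,h_in,h_in_sd,h_ex,h_ex_sd
SS1,44.9,9.49E-05,1.4E-05,0.15,0.02,0.12,0.02
SS2,51.7,1.04E-04,1.1E-05,0.16,0.02,0.14,0.01
SS3,47.0,9.87E-05,1.5E-05,0.15,0.02,0.13,0.02
SS4,23.2,4.80E-05,7.0E-06,0.07,0.01,0.06,0.01
SS5,51.6,1.10E-04,1.5E-05,0.17,0.02,0.14,0.02
SS6,15.6,3.35E-05,1.8E-06,0.05,0.00,0.04,0.00
SS7,58.1,1.18E-04,1.8E-05,0.20,0.03,0.17,0.02
SS8,34.7,7.04E-05,1.1E-05,0.13,0.02,0.09,0.01
SS9,67.0,1.34E-04,2.3E-05,0.22,0.05,0.19,0.03
SS10,17.3,3.70E-05,1.3E-06,0.06,0.00,0.05,0.00
SS11,69.8,1.36E-04,9.3E-06,0.25,0.02,0.19,0.01
SS12,38.5,7.66E-05,7.2E-06,0.12,0.01,0.10,0.01
SS13,23.3,4.87E-05,1.9E-06,0.08,0.00,0.06,0.00
SS14,30.4,6.35E-05,9.5E-06,0.10,0.01,0.08,0.01
SS15,81.2,1.62E-04,1.8E-05,0.24,0.03,0.22,0.02
SS16,20.0,4.22E-05,1.2E-05,0.07,0.02,0.05,0.02
SS17,54.6,1.10E-04,1.4E-05,0.17,0.03,0.15,0.02
SS18,60.6,1.25E-04,1.1E-05,0.19,0.02,0.16,0.02
SS19,54.6,1.11E-04,6.7E-06,0.16,0.01,0.15,0.01
SS20,42.9,8.56E-05,1.2E-06,0.15,0.00,0.12,0.00
SS21,52.3,1.05E-04,4.3E-06,0.17,0.01,0.14,0.01
SS22,31.1,6.47E-05,4.2E-06,0.11,0.01,0.08,0.01
SS23,50.2,1.13E-04,1.7E-05,0.15,0.02,0.14,0.02
SS24,27.8,5.59E-05,5.7E-06,0.09,0.01,0.08,0.01
SS25,33.4,7.02E-05,1.5E-05,0.11,0.03,0.09,0.02
SS26,34.1,6.85E-05,4.8E-06,0.11,0.01,0.09,0.01
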