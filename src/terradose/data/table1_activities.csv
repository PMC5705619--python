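sample_id,u_bqkg,th_bqkg,k_bqkg,u_sd,th_sd,k_sd
SS1,8.96,9.12,298,1.5,1.2,44.7
SS2,6.25,19.6,226,0.4,1.6,34.0
SS3,9.32,10.1,302,1.4,1.5,45.2
SS4,4.15,6.22,132,0.6,0.9,18.8
SS5,12.9,8.06,353,1.1,1.5,52.9
SS6,1.60,3.09,124,0.4,0.3,1.50
SS7,14.5,16.3,263,2.2,2.5,39.2
SS8,12.7,8.13,134,1.9,1.2,20.1
SS9,13.4,29.8,170,5.4,2.8,25.5
SS10,3.24,3.01,127,0.2,0.2,1.30
SS11,21.3,26.0,147,1.4,1.0,22.0
SS12,5.92,15.2,142,0.8,1.9,4.20
SS13,7.90,3.81,129,0.4,0.4,1.30
SS14,5.20,7.43,189,0.8,1.1,28.1
SS15,8.96,32.2,340,2.0,1.8,51.0
SS16,4.62,3.84,129,0.3,0.3,61.4
SS17,9.26,19.2,232,2.3,1.2,34.8
SS18,8.87,17.1,354,1.1,2.4,13.9
SS19,4.56,20.3,273,0.6,1.6,7.40
SS20,13.9,12.91,136,0.2,0.3,0.40
SS21,10.7,17.7,213,0.2,0.9,8.70
SS22,8.36,6.55,174,0.8,0.8,3.50
SS23,5.59,2.78,528,0.8,0.4,79.1
SS24,6.08,9.27,111,0.9,1.4,1.50
SS25,9.05,6.01,205,2.3,2.0,30.7
SS26,7.45,11.4,136,0.4,1.5,1.50
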