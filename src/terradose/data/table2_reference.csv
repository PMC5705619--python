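sample_id,d_ngy_h,d_sd,e_usv_y,e_sd,pct_u,pct_th,pct_k
SS1,22.1,3.3,2.71E+01,4.0E+00,18.7,24.9,56.3
SS2,24.2,2.5,2.97E+01,3.1E+00,12.0,49.0,39.0
SS3,22.9,3.5,2.82E+01,4.2E+00,18.7,26.6,54.7
SS4,11.2,1.6,1.37E+01,2.0E+00,17.1,33.6,49.3
SS5,25.5,3.6,3.13E+01,4.4E+00,23.3,19.1,57.6
SS6,7.8,0.4,9.56E+00,5.0E-01,9.49,24.0,66.6
SS7,27.5,4.1,3.38E+01,5.1E+00,24.3,35.6,39.9
SS8,16.4,2.5,2.01E+01,3.0E+00,35.9,30.0,34.2
SS9,31.2,5.2,3.83E+01,6.4E+00,19.8,57.5,22.7
SS10,8.6,0.3,1.06E+01,3.6E-01,17.4,21.1,61.6
SS11,31.7,2.2,3.89E+01,2.7E+00,31.1,49.6,19.3
SS12,17.8,1.7,2.19E+01,2.1E+00,15.3,51.4,33.3
SS13,11.3,0.4,1.39E+01,5.3E-01,32.2,20.3,47.5
SS14,14.8,2.2,1.81E+01,2.7E+00,16.3,30.4,53.4
SS15,37.8,4.2,4.64E+01,5.1E+00,11.0,51.5,37.5
SS16,9.8,2.9,1.21E+01,3.6E+00,21.7,23.6,54.6
SS17,25.6,3.3,3.14E+01,4.0E+00,16.7,45.5,37.8
SS18,29.2,2.6,3.58E+01,3.2E+00,14.0,35.4,50.6
SS19,25.8,1.6,3.16E+01,1.9E+00,8.18,47.7,44.2
SS20,19.9,0.3,2.45E+01,3.4E-01,32.3,39.1,28.5
SS21,24.5,1.0,3.01E+01,1.2E+00,20.2,43.6,36.3
SS22,15.1,1.0,1.85E+01,1.2E+00,25.6,26.3,48.1
SS23,26.3,3.9,3.22E+01,4.8E+00,9.8,36.39,83.8
SS24,13.02,1.3,1.60E+01,1.6E+00,21.6,43.0,35.4
SS25,16.33,3.5,2.01E+01,4.3E+00,25.6,22.2,52.2
SS26,15.9,1.1,1.96E+01,1.4E+00,21.6,43.0,35.4
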