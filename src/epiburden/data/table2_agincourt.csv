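sex,age_lo,age_hi,incidence_per_100k,incidence_lo,incidence_hi,prevalence_per_1000,prevalence_lo,prevalence_hi,remission_per_100,remission_lo,remission_hi,duration_years,duration_lo,duration_hi,smr,smr_lo,smr_hi
male,0,6,30.1,27.7,32.6,1.4,1.2,1.6,16.0,14.8,17.1,12.0,11.3,12.7,7.7,7.3,8.1
male,6,13,23.6,21.8,25.4,1.9,1.6,2.2,3.3,3.1,3.6,18.4,17.3,19.4,20.2,19.3,21.2
male,13,19,15.0,13.6,16.4,2.6,2.3,2.9,4.5,4.2,4.8,16.5,15.5,17.5,11.5,11.0,12.2
male,19,29,15.0,13.8,16.2,1.9,1.6,2.3,9.3,8.8,9.8,26.0,24.6,27.4,1.9,1.8,2.0
male,29,50,16.9,15.7,18.2,3.3,3.0,3.6,0.0,0.0,0.1,32.0,30.1,33.8,2.0,1.9,2.1
male,50,,19.7,18.3,21.2,5.6,5.1,6.0,2.0,1.6,2.4,25.3,22.3,28.5,3.6,3.4,3.7
male,,,19.4,17.9,21.0,2.6,2.3,2.9,4.6,4.1,5.0,21.5,20.1,22.8,8.2,7.9,8.7
female,0,6,16.0,13.1,18.0,0.4,0.3,0.5,30.5,28.5,32.6,10.6,,,1.0,1.0,1.0
female,6,13,19.3,17.2,20.2,0.9,0.7,1.0,6.6,5.6,7.3,28.2,26.7,29.6,1.0,1.0,1.0
female,13,19,17.8,16.2,18.8,1.9,1.7,2.1,0.4,0.2,0.6,27.2,25.8,28.7,3.7,3.6,4.0
female,19,29,13.0,11.9,14.1,2.8,2.5,3.0,1.3,0.9,1.7,22.4,21.3,23.6,2.7,2.8,2.9
female,29,50,16.1,15.0,17.4,3.9,3.5,4.2,3.1,2.8,3.4,16.6,15.7,17.5,1.3,1.1,1.4
female,50,,24.2,22.4,26.0,3.6,3.3,3.9,6.5,6.0,7.0,14.2,13.1,15.3,1.7,1.6,1.7
female,,,17.2,15.5,18.5,2.4,2.2,2.7,3.9,3.4,4.5,19.7,18.7,20.7,2.6,2.5,2.7
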