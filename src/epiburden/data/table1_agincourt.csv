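sex,age_lo,age_hi,person_years,deaths_all_cause,mortality_per_1000_pyo,mortality_lo,mortality_hi
male,0,6,20675,80,3.9,3.1,4.8
male,6,13,23729,31,1.3,0.9,1.9
male,13,19,19126,17,0.9,0.6,1.4
male,19,29,37381,163,4.4,3.7,5.1
male,29,50,31692,592,18.7,17.2,20.2
male,50,,13401,584,43.6,40.2,47.3
female,0,6,20539,52,2.5,1.9,3.3
female,6,13,24334,28,1.2,0.8,1.7
female,13,19,18385,17,0.9,0.6,1.5
female,19,29,34081,191,5.6,4.9,6.5
female,29,50,35511,424,11.9,10.9,13.1
female,50,,21773,638,29.3,27.1,31.7
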