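sex,population,incidence_per_100k,prevalence_per_1000,duration_years,dw,yld_incidence,yld_prevalence,pct_diff_yld,pct_diff_daly
male,39313,19.4,2.6,21.5,0.346,56.7,35.4,38,10
female,42443,17.2,2.4,19.7,0.346,49.8,35.2,29,10
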