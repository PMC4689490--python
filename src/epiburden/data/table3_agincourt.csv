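sex,age_lo,age_hi,yll,yll_lo,yll_hi,yld,yld_lo,yld_hi,daly,daly_lo,daly_hi
male,0,6,0,0,0,2.8,1.4,4.5,2.8,1.4,4.5
male,6,13,58.4,0,118.8,6.6,4.2,9.3,64.9,5.2,151.3
male,13,19,0,0,0,6.9,4.5,9.3,6.9,4.5,9.3
male,19,29,0,0,0,6.6,4.2,9.3,6.6,4.2,9.3
male,29,50,38.2,0,93.5,15.6,11.8,19.4,53.7,13.8,95.7
male,50,,55.1,14.1,101.8,6.2,4.1,8.6,61.4,19.3,112.5
male,,,151.6,66.3,249.1,44.6,38.4,50.5,196.3,109.8,295.5
female,0,6,0,0,0,0.7,0,1.7,0.7,0,1.7
female,6,13,0,0,0,3.5,1.7,5.5,3.5,1.7,5.5
female,13,19,0,0,0,4.8,2.8,7.3,4.8,2.8,7.3
female,19,29,47.8,0,118.2,9.7,6.9,12.8,57.4,8.3,110.6
female,29,50,21.7,0,65.2,14.5,11.1,18.3,36.3,11.8,79.4
female,50,,26.2,0,63.9,6.9,4.5,9.4,33.2,5.5,69.7
female,,,95.7,33.0,168.6,40.1,33.9,46.4,135.9,66.9,210.2
both,0,6,0,0,0,3.5,1.7,5.2,3.5,1.7,5.2
both,6,13,58.4,0,145.7,10.0,7.3,13.2,68.4,8.6,155.4
both,13,19,0,0,0,11.8,8.6,15.2,11.8,8.6,15.2
both,19,29,47.8,0,118.2,16.3,12.5,20.1,64.0,14.5,130.5
both,29,50,59.9,18.42,118.4,30.1,24.9,35.3,90.0,33.5,151.7
both,50,,81.4,26.88,137.2,13.2,10.0,16.6,94.5,40.0,155.1
both,,,247.4,129.4,373.2,84.8,76.5,93.8,332.1,215.9,454.8
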