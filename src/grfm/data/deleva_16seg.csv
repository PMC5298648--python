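segment,mass_pct,com_pct,rx_pct,ry_pct,rz_pct
head,6.94,50.02,30.3,31.5,26.1
upper_trunk,15.96,50.66,50.5,32,46.5
middle_trunk,16.33,45.02,48.2,38.3,46.8
pelvis,11.17,61.15,61.5,55.1,58.7
upper_arm,2.71,57.72,28.5,26.9,15.8
forearm,1.62,45.74,27.6,26.5,12.1
hand,0.61,36.24,28.8,23.5,18.4
upper_leg,14.16,40.95,32.9,32.9,14.9
lower_leg,4.33,43.95,25.1,24.6,10.2
foot,1.37,44.15,25.7,24.5,12.4
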