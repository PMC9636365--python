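kind,name,BL,LT,MT1,MT2,MAL,RE
parameter,poms_fatigue,0,2,1,3,9,1
parameter,hr_max,1,0,5,5,10,2
parameter,glucose_end,2,2,0,7,9,0
parameter,lactate_end,4,3,7,6,7,1
parameter,rpe_mean,0,0,0,5,9,9
cumulative,1,5,6,9,9,11,9
cumulative,2,2,1,4,6,11,4
cumulative,3,0,0,0,6,11,0
cumulative,4,0,0,0,4,6,0
cumulative,5,0,0,0,1,5,0
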