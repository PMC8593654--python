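compound,time_window,max_20min,composite,composite_below_loq,loq,aqs,rac
azoxystrobin,2019-07-01,6300,490,False,,550,3300
diuron,2019-07-07,490,,True,15,250,1830
fluopyram,2019-07-01,30900,2690,False,,25100,13500
nicosulfuron,2019-07-01,280,32,False,,230,230
thiacloprid,2019-07-07,2280,270,False,,80,200
carbendazim,2019-05-02,,790,False,,700,
chlorpyrifos-methyl,2019-05-09,,10,False,,7.3,30
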