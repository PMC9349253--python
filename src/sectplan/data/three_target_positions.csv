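target,axis,foreknown,run1,run2,run3,run4
Red,X,2000,1900,2100,2000,1900
Red,Y,1000,900,1100,1000,1100
Red,Z,4000,4100,4200,4000,4000
Green,X,8000,7900,8100,8000,7800
Green,Y,3000,2900,2900,3100,3100
Green,Z,5000,5100,5200,5100,5100
Blue,X,5000,4900,4900,5100,5100
Blue,Y,7000,7200,7100,7100,7200
Blue,Z,6000,6100,6300,6000,6200
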