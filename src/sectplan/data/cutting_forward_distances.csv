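target,run,actual,expected
Red,1,6050,6100
Red,2,7050,6700
Red,3,6680,6118
Red,4,6150,6380
Green,1,6150,6100
Green,2,7150,6700
Green,3,6070,6118
Green,4,6160,6380
Blue,1,6040,6100
Blue,2,6500,6700
Blue,3,6472,6118
Blue,4,6850,6380
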