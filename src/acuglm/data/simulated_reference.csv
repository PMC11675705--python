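name,true,estimate
k1,0.85,0.843
h11,1,0.978
h12,1.4,1.414
h13,0.8,0.787
k2,0.9,0.897
h22,1.25,1.203
h21,1,0.980
h23,0.7,0.701
k3,0.7,0.699
h33,1,1.002
h31,0.9,0.876
h32,1.2,1.173
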