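manipulation,neuron,k,h1,h2,h3
twirling,1,-0.0003,0.2021,0.0970,0.6380
twirling,2,0.0027,2.6788,0.1397,0.9413
twirling,3,0.0003,3.5635,0.2568,0.0493
lifting_thrusting,1,0.0100,0.1662,0.4911,0.6562
lifting_thrusting,2,-0.0295,1.5872,-0.0352,1.5511
lifting_thrusting,3,-0.0153,1.6837,1.2613,-0.0622
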