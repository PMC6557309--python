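stage,transporter,cell_type,upper_outer,upper_inner,inner_upper,inner_lower,lower_inner,lower_outer,outer_lower,outer_upper
17b,PIN3,replum,0,0,0,0,0.8,0.8,0,0
17b,PIN3,separation_layer,0.2,0.2,0.2,0.2,0.2,0.2,0.2,0.2
17b,PIN3,lignifying_layer,0.2,0.2,0.2,0.2,0.2,0.2,0.2,0.2
17b,PIN3,valve,0,0,0,0.4,1,1,0.4,0
17b,PIN7,valve,0,0,0,0,1,1,0,0
17b,LAX1,replum,1,1,1,1,1,1,1,1
17b,LAX1,valve,0.2,0.2,0.2,0.2,0.2,0.2,0.2,0.2
16,PIN3,replum,0.8,0.8,0.4,0.4,0.8,0.8,0.4,0.4
16,PIN3,separation_layer,0.2,0.2,0.2,0.2,0.2,0.2,0.2,0.2
16,PIN3,lignifying_layer,0.2,0.2,0.2,0.2,0.2,0.2,0.2,0.2
16,PIN3,valve,0,0,0,0.4,1,1,0.4,0
16,PIN7,replum,0,0,0,0,0.1,0.1,0,0
16,PIN7,valve,0,0,0.2,0.2,1,1,0.2,0.2
16,LAX1,replum,1,1,1,1,1,1,1,1
16,LAX1,valve,0.8,0.8,0.8,0.8,0.8,0.8,0.8,0.8
15,PIN3,replum,0.8,0.8,0.4,0.4,0.8,0.8,0.4,0.4
15,PIN3,valve,0,0,0,0.4,1,1,0.4,0
15,PIN7,replum,0,0,0,0,0.1,0.1,0,0
15,PIN7,valve,0,0,0.2,0.2,1,1,0.2,0.2
15,LAX1,replum,1,1,1,1,1,1,1,1
15,LAX1,valve,0.8,0.8,0.8,0.8,0.8,0.8,0.8,0.8
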