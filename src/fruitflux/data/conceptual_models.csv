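model,transporter,cell_type,upper_outer,upper_inner,inner_upper,inner_lower,lower_inner,lower_outer,outer_lower,outer_upper
basic,PIN3,replum,0,0,0,0.5,1,1,0.5,0
basic,PIN3,valve,0,0,0,0.5,1,1,0.5,0
import,PIN3,replum,0,0,0,0.5,1,1,0.5,0
import,PIN3,valve,0,0,0,0.5,1,1,0.5,0
import,LAX1,replum,1,1,1,1,1,1,1,1
import,LAX1,valve,1,1,1,1,1,1,1,1
export,PIN3,replum,0,0,0,0.5,1,1,0.5,0
export,PIN3,separation_layer,1,1,1,1,1,1,1,1
export,PIN3,lignifying_layer,1,1,1,1,1,1,1,1
export,PIN3,valve,0,0,0,0.5,1,1,0.5,0
combined,PIN3,replum,0,0,0,0.5,1,1,0.5,0
combined,PIN3,separation_layer,1,1,1,1,1,1,1,1
combined,PIN3,lignifying_layer,1,1,1,1,1,1,1,1
combined,PIN3,valve,0,0,0,0.5,1,1,0.5,0
combined,LAX1,replum,1,1,1,1,1,1,1,1
combined,LAX1,valve,1,1,1,1,1,1,1,1
production_decay,PIN3,replum,0,0,0,0.5,1,1,0.5,0
production_decay,PIN3,separation_layer,0,0,0,0.5,1,1,0.5,0
production_decay,PIN3,lignifying_layer,0,0,0,0.5,1,1,0.5,0
production_decay,PIN3,valve,0,0,0,0.5,1,1,0.5,0
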