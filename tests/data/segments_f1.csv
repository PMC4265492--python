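segment_id,tissue_ml,air_ml
LB1,40,600
LB2,45,620
LB3,70,630
LB4,30,270
LB5,35,280
RB1,38,560
RB2,55,590
RB3,60,540
LLL,150,1000
RLL,140,1000
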