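compound_id,core_id,value_id,class
A,c1,v1,active
B,c1,v2,active
C,c1,v4,inactive
D,c2,v1,inactive
E,c2,v3,active
F,c2,v4,active
G,c3,v2,active
H,c3,v3,inactive
I,c3,v4,inactive
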