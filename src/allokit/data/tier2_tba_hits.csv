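compound_id,receptor_id,affinity,pose_rank
NSC-103858,wtSHP2-b,-7.4,1
NSC-106445,wtSHP2-b,-7.7,1
NSC-118695,wtSHP2-b,-7.5,1
NSC-121342,wtSHP2-b,-7.3,1
NSC-121974,wtSHP2-b,-8.4,1
NSC-210399,wtSHP2-b,-7.5,1
NSC-252124,wtSHP2-b,-7.4,1
NSC-261054,wtSHP2-b,-7.4,1
NSC-30502,wtSHP2-b,-8.1,1
NSC-39355,wtSHP2-b,-7.3,1
NSC-39913,wtSHP2-b,-7.5,1
NSC-39917,wtSHP2-b,-7.5,1
NSC-60678,wtSHP2-b,-8.4,1
NSC-67586,wtSHP2-b,-7.4,1
NSC-163300,wtSHP2-b,-8.6,1
NSC-23127,wtSHP2-b,-6.2,1
NSC-250352,wtSHP2-b,-8.2,1
NSC-74702,wtSHP2-b,-7.8,1
NSC-103858,mtSHP2-b,-7.5,1
NSC-106445,mtSHP2-b,-7.9,1
NSC-118695,mtSHP2-b,-7.5,1
NSC-121342,mtSHP2-b,-7.2,1
NSC-121974,mtSHP2-b,-7.6,1
NSC-210399,mtSHP2-b,-7.2,1
NSC-252124,mtSHP2-b,-7.6,1
NSC-261054,mtSHP2-b,-7.3,1
NSC-30502,mtSHP2-b,-7.6,1
NSC-39355,mtSHP2-b,-7.4,1
NSC-39913,mtSHP2-b,-7.4,1
NSC-39917,mtSHP2-b,-7.7,1
NSC-60678,mtSHP2-b,-8.3,1
NSC-67586,mtSHP2-b,-7.4,1
NSC-163300,mtSHP2-b,-7.9,1
NSC-23127,mtSHP2-b,-7.5,1
NSC-250352,mtSHP2-b,-7.4,1
NSC-74702,mtSHP2-b,-7.9,1
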