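compound_id,receptor_id,affinity,pose_rank
NSC-14757,wtSHP2-b,-7.9,1
NSC-153191,wtSHP2-b,-8.1,1
NSC-211584,wtSHP2-b,-7.3,1
NSC-299137,wtSHP2-b,-7.8,1
NSC-371876,wtSHP2-b,-7.4,1
NSC-380323,wtSHP2-b,-7.6,1
NSC-39909,wtSHP2-b,-7.5,1
NSC-39918,wtSHP2-b,-9.7,1
NSC-618161,wtSHP2-b,-7.6,1
NSC-637201,wtSHP2-b,-7.8,1
NSC-649243,wtSHP2-b,-7.2,1
NSC-649245,wtSHP2-b,-7.7,1
NSC-665127,wtSHP2-b,-7.9,1
NSC-747599,wtSHP2-b,-7.3,1
NSC-85195,wtSHP2-b,-7.3,1
NSC-103851,wtSHP2-b,-7.4,1
NSC-252174,wtSHP2-b,-8.9,1
NSC-400376,wtSHP2-b,-7.7,1
NSC-53298,wtSHP2-b,-7.1,1
NSC-63675,wtSHP2-b,-7.1,1
NSC-74671,wtSHP2-b,-7.1,1
NSC-14757,mtSHP2-b,-8.1,1
NSC-153191,mtSHP2-b,-7.6,1
NSC-211584,mtSHP2-b,-7.1,1
NSC-299137,mtSHP2-b,-7.7,1
NSC-371876,mtSHP2-b,-7.3,1
NSC-380323,mtSHP2-b,-7.5,1
NSC-39909,mtSHP2-b,-7.4,1
NSC-39918,mtSHP2-b,-7.5,1
NSC-618161,mtSHP2-b,-7.5,1
NSC-637201,mtSHP2-b,-8.1,1
NSC-649243,mtSHP2-b,-7.2,1
NSC-649245,mtSHP2-b,-7.5,1
NSC-665127,mtSHP2-b,-7.6,1
NSC-747599,mtSHP2-b,-7.2,1
NSC-85195,mtSHP2-b,-7.2,1
NSC-103851,mtSHP2-b,-7.4,1
NSC-252174,mtSHP2-b,-7.8,1
NSC-400376,mtSHP2-b,-7.5,1
NSC-53298,mtSHP2-b,-7.7,1
NSC-63675,mtSHP2-b,-7.2,1
NSC-74671,mtSHP2-b,-7.3,1
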