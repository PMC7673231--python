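subject_id,group,word_id,target_tone,onset_st,mid_st,offset_st
T1,NH,w01,1,0,0,0
T1,NH,w02,1,1,0,0
T1,NH,w03,1,0,0,1
T1,NH,w04,2,5,0,0
T1,NH,w05,2,6,0,0
T1,NH,w06,2,5,0,1
T1,NH,w07,3,0,0,5
T1,NH,w08,3,1,0,5
T1,NH,w09,3,0,0,6
T1,NH,w10,4,5,0,5
T1,NH,w11,4,6,0,5
T1,NH,w12,4,5,0,6
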