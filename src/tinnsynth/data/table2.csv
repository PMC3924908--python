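participant,similarity_audiometer,similarity_synthesizer,duration_audiometer,duration_synthesizer
1,7,9,4,2
2,6,9,6,2
3,3,8,4,2
4,2,9,5,4
5,3,3,8,6
6,6,9,10,8
7,7,9,6,2
8,9,10,6,1
9,8,8,5,2
10,8,5,3,4
11,5,5,3,2
12,7,8,5,3
13,7,8,9,4
14,1,9,2,6
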