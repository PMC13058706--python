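marker,clone,host,position_1,position_2,position_3,position_4,position_5,final_position
CD79a,SP18,rabbit,0,30.64,11.70,10.38,12.78,2
CD38,SPC32,mouse,0,-1.85,-4.10,-19.20,-15.88,1
Ki-67,D3B5,rabbit,0,14.84,38.94,38.57,5.31,4
CD138,B-A38,mouse,0,40.83,42.98,24.52,13.10,5
CD19,LE-CD19,mouse,0,-21.57,278.06,163.59,197.18,3
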