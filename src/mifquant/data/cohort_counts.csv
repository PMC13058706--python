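cohort,n_slides,gate,count
TN,2,b_cell,355850
TN,2,plasma_cell,31831
TN,2,permissive_pb,3812
TN,2,bona_fide_pb,3352
KD,8,b_cell,3750
KD,8,plasma_cell,3807
KD,8,permissive_pb,282
KD,8,bona_fide_pb,212
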