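place_id,k,label
r00c00,2,0
r00c01,2,0
r00c02,2,0
r00c03,2,0
r01c00,2,0
r01c01,2,0
r01c02,2,0
r01c03,2,0
r02c00,2,1
r02c01,2,1
r02c02,2,0
r02c03,2,0
r03c00,2,1
r03c01,2,1
r03c02,2,0
r03c03,2,0
r00c00,4,0
r00c01,4,0
r00c02,4,1
r00c03,4,1
r01c00,4,0
r01c01,4,0
r01c02,4,1
r01c03,4,1
r02c00,4,2
r02c01,4,2
r02c02,4,3
r02c03,4,3
r03c00,4,2
r03c01,4,2
r03c02,4,3
r03c03,4,3
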