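place_id,user_count
r00c00,142
r00c01,130
r00c02,128
r00c03,128
r01c00,129
r01c01,169
r01c02,168
r01c03,91
r02c00,54
r02c01,105
r02c02,95
r02c03,141
r03c00,94
r03c01,35
r03c02,124
r03c03,120
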