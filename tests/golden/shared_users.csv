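place_i,place_j,kind,value
r00c00,r00c01,shared_users,91
r00c00,r00c02,shared_users,58
r00c00,r00c03,shared_users,50
r00c00,r01c00,shared_users,93
r00c00,r01c01,shared_users,110
r00c00,r01c02,shared_users,73
r00c00,r01c03,shared_users,35
r00c00,r02c00,shared_users,31
r00c00,r02c01,shared_users,47
r00c00,r02c02,shared_users,29
r00c00,r02c03,shared_users,40
r00c00,r03c00,shared_users,45
r00c00,r03c01,shared_users,17
r00c00,r03c02,shared_users,38
r00c00,r03c03,shared_users,27
r00c01,r00c02,shared_users,60
r00c01,r00c03,shared_users,47
r00c01,r01c00,shared_users,81
r00c01,r01c01,shared_users,98
r00c01,r01c02,shared_users,71
r00c01,r01c03,shared_users,28
r00c01,r02c00,shared_users,16
r00c01,r02c01,shared_users,33
r00c01,r02c02,shared_users,23
r00c01,r02c03,shared_users,37
r00c01,r03c00,shared_users,29
r00c01,r03c01,shared_users,10
r00c01,r03c02,shared_users,35
r00c01,r03c03,shared_users,28
r00c02,r00c03,shared_users,89
r00c02,r01c00,shared_users,43
r00c02,r01c01,shared_users,69
r00c02,r01c02,shared_users,95
r00c02,r01c03,shared_users,59
r00c02,r02c00,shared_users,9
r00c02,r02c01,shared_users,34
r00c02,r02c02,shared_users,27
r00c02,r02c03,shared_users,53
r00c02,r03c00,shared_users,22
r00c02,r03c01,shared_users,7
r00c02,r03c02,shared_users,31
r00c02,r03c03,shared_users,39
r00c03,r01c00,shared_users,40
r00c03,r01c01,shared_users,56
r00c03,r01c02,shared_users,94
r00c03,r01c03,shared_users,66
r00c03,r02c00,shared_users,14
r00c03,r02c01,shared_users,31
r00c03,r02c02,shared_users,37
r00c03,r02c03,shared_users,65
r00c03,r03c00,shared_users,25
r00c03,r03c01,shared_users,9
r00c03,r03c02,shared_users,41
r00c03,r03c03,shared_users,49
r01c00,r01c01,shared_users,102
r01c00,r01c02,shared_users,59
r01c00,r01c03,shared_users,23
r01c00,r02c00,shared_users,26
r01c00,r02c01,shared_users,36
r01c00,r02c02,shared_users,32
r01c00,r02c03,shared_users,44
r01c00,r03c00,shared_users,40
r01c00,r03c01,shared_users,16
r01c00,r03c02,shared_users,36
r01c00,r03c03,shared_users,33
r01c01,r01c02,shared_users,85
r01c01,r01c03,shared_users,36
r01c01,r02c00,shared_users,41
r01c01,r02c01,shared_users,62
r01c01,r02c02,shared_users,45
r01c01,r02c03,shared_users,55
r01c01,r03c00,shared_users,57
r01c01,r03c01,shared_users,23
r01c01,r03c02,shared_users,51
r01c01,r03c03,shared_users,40
r01c02,r01c03,shared_users,69
r01c02,r02c00,shared_users,27
r01c02,r02c01,shared_users,62
r01c02,r02c02,shared_users,51
r01c02,r02c03,shared_users,83
r01c02,r03c00,shared_users,47
r01c02,r03c01,shared_users,18
r01c02,r03c02,shared_users,63
r01c02,r03c03,shared_users,64
r01c03,r02c00,shared_users,8
r01c03,r02c01,shared_users,19
r01c03,r02c02,shared_users,21
r01c03,r02c03,shared_users,41
r01c03,r03c00,shared_users,21
r01c03,r03c01,shared_users,8
r01c03,r03c02,shared_users,33
r01c03,r03c03,shared_users,34
r02c00,r02c01,shared_users,39
r02c00,r02c02,shared_users,16
r02c00,r02c03,shared_users,19
r02c00,r03c00,shared_users,41
r02c00,r03c01,shared_users,21
r02c00,r03c02,shared_users,21
r02c00,r03c03,shared_users,15
r02c01,r02c02,shared_users,36
r02c01,r02c03,shared_users,54
r02c01,r03c00,shared_users,59
r02c01,r03c01,shared_users,27
r02c01,r03c02,shared_users,52
r02c01,r03c03,shared_users,47
r02c02,r02c03,shared_users,67
r02c02,r03c00,shared_users,34
r02c02,r03c01,shared_users,11
r02c02,r03c02,shared_users,62
r02c02,r03c03,shared_users,62
r02c03,r03c00,shared_users,42
r02c03,r03c01,shared_users,21
r02c03,r03c02,shared_users,90
r02c03,r03c03,shared_users,89
r03c00,r03c01,shared_users,27
r03c00,r03c02,shared_users,46
r03c00,r03c03,shared_users,41
r03c01,r03c02,shared_users,21
r03c01,r03c03,shared_users,16
r03c02,r03c03,shared_users,77
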