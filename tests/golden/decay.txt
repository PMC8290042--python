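origin=r01c01 a=8.61918 b=0.6345 R2=0.5214 n=15
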