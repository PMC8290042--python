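term             coefficient          SE  sig
intercept           0.476534     0.02691  ***
same_parent         0.207181     0.02307  ***
distance        -0.000980888   0.0001547  ***
Adjusted R2: 0.7022
Observations: 120
*p < 0.1, **p < 0.05, ***p < 0.01
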