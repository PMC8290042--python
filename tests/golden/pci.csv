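place_i,place_j,kind,value
r00c00,r00c01,pci,0.66976977335183963
r00c00,r00c02,pci,0.43020835109527183
r00c00,r00c03,pci,0.37086926818557914
r00c00,r01c00,pci,0.68713792836001586
r00c00,r01c01,pci,0.71007653394335224
r00c00,r01c02,pci,0.47263300605984948
r00c00,r01c03,pci,0.30789538260674282
r00c00,r02c00,pci,0.3540141667442247
r00c00,r02c01,pci,0.38490985992603038
r00c00,r02c02,pci,0.24968475305488733
r00c00,r02c03,pci,0.282687277205107
r00c00,r03c00,pci,0.38949726708518317
r00c00,r03c01,pci,0.24114081645412283
r00c00,r03c02,pci,0.28637070049302049
r00c00,r03c03,pci,0.20683735189961475
r00c01,r00c02,pci,0.46513025470953173
r00c01,r00c03,pci,0.36435203285579987
r00c01,r01c00,pci,0.62548728767921458
r00c01,r01c01,pci,0.66116681455452975
r00c01,r01c02,pci,0.48043211624018045
r00c01,r01c03,pci,0.25743385431817706
r00c01,r02c00,pci,0.19096396641051544
r00c01,r02c01,pci,0.28245392505720252
r00c01,r02c02,pci,0.20696378450628988
r00c01,r02c03,pci,0.27328795546309798
r00c01,r03c00,pci,0.26233871984132823
r00c01,r03c01,pci,0.14824986333222023
r00c01,r03c02,pci,0.27566747329212693
r00c01,r03c03,pci,0.22417941532712199
r00c02,r00c03,pci,0.6953125
r00c02,r01c00,pci,0.33463288342102104
r00c02,r01c01,pci,0.46913815290261329
r00c02,r01c02,pci,0.64783436163810237
r00c02,r01c03,pci,0.54667137103756214
r00c02,r02c00,pci,0.10825317547305482
r00c02,r02c01,pci,0.29327786272050055
r00c02,r02c02,pci,0.24484823441212894
r00c02,r02c03,pci,0.39451300889121155
r00c02,r03c00,pci,0.20056436330960503
r00c02,r03c01,pci,0.10458250331675945
r00c02,r03c02,pci,0.2460627460628691
r00c02,r03c03,pci,0.31467989687935261
r00c03,r01c00,pci,0.31128640318234518
r00c03,r01c01,pci,0.38074980525429486
r00c03,r01c02,pci,0.64101505256822766
r00c03,r01c03,pci,0.61153068624540852
r00c03,r02c00,pci,0.16839382851364085
r00c03,r02c01,pci,0.26740040424516226
r00c03,r02c02,pci,0.33553276567588042
r00c03,r02c03,pci,0.48383670901752363
r00c03,r03c00,pci,0.22791404921546024
r00c03,r03c01,pci,0.13446321855011928
r00c03,r03c02,pci,0.32543782543798816
r00c03,r03c03,pci,0.39536704992534044
r01c00,r01c01,pci,0.69081532650164323
r01c00,r01c02,pci,0.40077674675345099
r01c00,r01c03,pci,0.21228156695322095
r01c00,r02c00,pci,0.31151690036548879
r01c00,r02c01,pci,0.30932355733588024
r01c00,r02c02,pci,0.28906354238843002
r01c00,r02c03,pci,0.326248305753428
r01c00,r03c00,pci,0.36324630842882361
r01c00,r03c01,pci,0.23811738545941744
r01c00,r03c02,pci,0.28464057171065044
r01c00,r03c03,pci,0.26523355219372668
r01c01,r01c02,pci,0.50445325949145436
r01c01,r01c03,pci,0.29029426247683893
r01c01,r02c00,pci,0.4291841002312406
r01c01,r02c01,pci,0.46542926556006964
r01c01,r02c02,pci,0.35514635264486105
r01c01,r02c03,pci,0.35629504352814262
r01c01,r03c00,pci,0.45223854643654787
r01c01,r03c01,pci,0.29905458244239819
r01c01,r03c02,pci,0.35230270782175077
r01c01,r03c03,pci,0.28088336282316212
r01c02,r01c03,pci,0.55805082397126504
r01c02,r02c00,pci,0.28347335475692043
r01c02,r02c01,pci,0.46681241650104649
r01c02,r02c02,pci,0.40369533662408102
r01c02,r02c03,pci,0.53927947977993662
r01c02,r03c00,pci,0.37400662077154784
r01c02,r03c01,pci,0.23473823893078549
r01c02,r03c02,pci,0.43649077143553344
r01c02,r03c03,pci,0.45074893585520881
r01c03,r02c00,pci,0.11412279800291011
r01c03,r02c01,pci,0.19437403723927466
r01c03,r02c02,pci,0.22585868535211981
r01c03,r02c03,pci,0.3619541865188089
r01c03,r03c00,pci,0.22705688307244251
r01c03,r03c01,pci,0.14175398238766679
r01c03,r03c02,pci,0.31065789927072207
r01c03,r03c03,pci,0.32536257599915491
r02c00,r02c01,pci,0.51793239737823726
r02c00,r02c02,pci,0.22338875108890427
r02c00,r02c03,pci,0.21774448532130083
r02c00,r03c00,pci,0.57547047939545459
r02c00,r03c01,pci,0.48304589153964794
r02c00,r03c02,pci,0.25663245128736828
r02c00,r03c03,pci,0.18633899812498247
r02c01,r02c02,pci,0.3604508455116664
r02c01,r02c03,pci,0.44380230544938415
r02c01,r03c00,pci,0.59387280098412787
r02c01,r03c01,pci,0.4453844933748542
r02c01,r03c02,pci,0.45571975110966967
r02c01,r03c03,pci,0.41870927899613153
r02c02,r02c03,pci,0.57889985892138651
r02c02,r03c00,pci,0.35979339598435234
r02c02,r03c01,pci,0.19076419329530639
r02c02,r03c02,pci,0.57124057057747935
r02c02,r03c03,pci,0.58068320318065025
r02c03,r03c00,pci,0.36481762126557971
r02c03,r03c01,pci,0.29893427727120819
r02c03,r03c02,pci,0.68064727561011373
r02c03,r03c03,pci,0.68421064595475645
r03c00,r03c01,pci,0.47072342953422447
r03c00,r03c02,pci,0.42607206623762922
r03c00,r03c03,pci,0.38603733329178858
r03c01,r03c02,pci,0.31876778887743107
r03c01,r03c03,pci,0.24688535993934707
r03c02,r03c03,pci,0.63123236694205476
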