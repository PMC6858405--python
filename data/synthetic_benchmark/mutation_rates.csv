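species,mutation_rate,genome_size
Mesoplasma_florum,1.9471507142534812e-11,9.841752675329062
Escherichia_coli,5.834514936002298e-11,3.1964197724339236
Salmonella_enterica,4.793838147409555e-10,1.8983069277427143
Bacillus_subtilis,3.640148623594206e-09,3.4854230019093406
Pseudomonas_aeruginosa,5.142169610874743e-10,2.601871904109475
Deinococcus_radiodurans,2.156470612696079e-10,2.6319091125138883
Mycobacterium_smegmatis,3.0844397746373796e-11,4.4971725770602236
Vibrio_cholerae,2.3679576896281925e-10,4.177674935496517
Caulobacter_crescentus,3.1429998792343266e-10,4.236300089520192
Staphylococcus_aureus,5.302748793843235e-09,1.071202942547346
Helicobacter_pylori,9.077116517919438e-10,5.325463421592979
Teredinibacter_turnerae,2.5975247230212562e-11,6.151697073395498
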