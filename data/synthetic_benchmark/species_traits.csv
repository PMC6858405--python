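species,genome_size,gc,pin_pis,lab_dt,rrn_copies,trna_count,mutation_rate,lifestyle
Buchnera_aphidicola,1.6788881349377902,36.87099251523921,,0.4598114536599436,3,40,,obligate
Campylobacter_jejuni,2.1867137576851254,20.379062268124287,0.12017254939507047,0.8465819369875403,9,72,,opportunistic
Clostridioides_difficile,3.2314622540623783,35.39810935084709,0.18215181326573573,34.68274008025464,6,42,,opportunistic
Escherichia_coli,3.168677343847404,53.46246319113151,0.24569148354534348,5.868936846625506,10,50,1.0323926238593578e-10,obligate
Helicobacter_pylori,2.2235997114317896,39.94384660872801,0.16118449196391613,0.8878900338126737,3,65,3.6376039337362787e-10,obligate
Mycobacterium_leprae,4.6116930322834735,51.12277553809899,0.1868077017368152,0.4990812352485093,4,40,,obligate
Mycobacterium_tuberculosis,2.6057257653371515,32.57055038661444,0.12739044208519798,0.726085436954595,9,90,,opportunistic
Salmonella_enterica,3.774570412660698,38.95863980312198,0.13742777958678076,1.9509184379267255,2,71,7.223685521368468e-11,obligate
Staphylococcus_aureus,2.136431722034698,48.1932725353646,0.24110790433159116,2.0683665456858256,4,43,,obligate
Streptococcus_pneumoniae,3.834735532595478,48.986724841148884,0.2656459921700352,0.9226515795559145,4,52,,opportunistic
Vibrio_cholerae,2.884564443846389,46.763048661298804,0.16240812354451548,0.5260675214204481,8,69,4.893745535677951e-11,opportunistic
Yersinia_pestis,5.228421161633175,62.56597769732015,0.18815621710753416,8.711046406343325,8,50,,obligate
Acinetobacter_baumannii,3.4198190547634724,41.32043048885028,0.2131097848512551,3.1860930341635054,8,67,,opportunistic
Bacillus_anthracis,3.0678788346585053,39.736686407214044,0.10522415047027592,1.3534567775470827,5,87,,opportunistic
Bordetella_pertussis,3.3496862702260874,31.97192842457372,0.15645187258063006,1.587458777350878,7,52,,obligate
Borrelia_burgdorferi,6.182828529249516,66.99191379738113,0.250696695642904,1.152686729747093,6,42,,opportunistic
Brucella_abortus,3.541118521143919,39.68664593986675,0.16620482221940594,0.09523126412149999,8,47,,opportunistic
Burkholderia_pseudomallei,3.6081595885328555,53.394906340681615,0.3447187573344687,2.249302273367463,2,61,,obligate
Chlamydia_trachomatis,3.269849388465559,58.701107344693916,0.1772321435583116,0.6580441242852179,4,63,,opportunistic
Enterococcus_faecium,3.3394635166566506,44.364426812620295,0.23874327948801316,0.705979459523663,8,31,,obligate
Francisella_tularensis,4.333094899020189,49.21220906203998,0.16246481378492392,1.0277368238022164,3,69,,opportunistic
Haemophilus_influenzae,1.6591527179901997,36.1790928263498,0.08839460798858617,4.261237807596559,3,39,,opportunistic
Klebsiella_pneumoniae,4.58608383213188,36.1770237914411,0.09568571042433048,0.5932819508825714,10,68,,opportunistic
Legionella_pneumophila,3.1340569915288707,58.61344583542089,0.16542235769785707,0.4514122528800505,2,83,,obligate
Leptospira_interrogans,1.2386638638643812,42.28806623277547,0.24048957152312467,3.8719829283502714,10,41,,opportunistic
Listeria_monocytogenes,3.665899437331144,38.7842753633614,0.14187564648997342,4.359794378685076,9,78,,opportunistic
Moraxella_catarrhalis,4.770968457650438,47.90111964699239,0.16198441065691616,0.7387199562605778,2,32,,obligate
Neisseria_gonorrhoeae,5.350036971380125,55.09716559531406,0.1362202842397058,3.5733779629546163,6,63,,obligate
Neisseria_meningitidis,4.378269458460537,50.966198083257254,0.24248125990205915,1.4749096132922306,4,70,,obligate
Pseudomonas_aeruginosa,2.56181533108317,31.188926029292936,0.1892673728443433,2.7263491904949455,5,43,7.532505925401857e-10,opportunistic
Shigella_sonnei,3.5322523286151206,44.36144851276082,0.1388708806874907,0.5402165362290833,7,77,,obligate
Streptococcus_pyogenes,4.864849960799588,54.63591808741483,0.17182848567558315,4.72936139759289,9,64,,obligate
Treponema_pallidum,2.449668663996457,40.30789615928981,0.1689474447969453,6.941711005701254,10,55,,obligate
Xanthomonas_oryzae,3.309788245033584,44.77469833660885,0.16554114841036052,3.860850240854875,1,30,,opportunistic
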