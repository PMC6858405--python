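species,rate,sampling_time,site_class,hypermutator,study
Buchnera_aphidicola,1.5871356245843032e-07,888.3278369442148,all,False,study001
Campylobacter_jejuni,4.460057484057368e-05,2.648850432503029,all,False,study002
Campylobacter_jejuni,0.00012060109334258356,70.24371086602216,all,False,study003
Clostridioides_difficile,1.4562944763015381e-05,32.19793560414048,all,False,study004
Clostridioides_difficile,9.581415191615856e-06,38.03192071044708,all,False,study005
Escherichia_coli,1.4925195543042637e-06,15.612254715469644,all,False,study006
Escherichia_coli,5.405470807113719e-06,4.68944224006121,all,False,study007
Escherichia_coli,3.6573091450251935e-06,1.6462217758700795,all,False,study008
Helicobacter_pylori,1.001097159108718e-06,571.5014722856114,all,False,study009
Helicobacter_pylori,2.9642140667372803e-06,1098.791277700573,all,False,study010
Helicobacter_pylori,2.3709609447966163e-06,21.118339003341806,all,False,study011
Mycobacterium_leprae,1.35264405518893e-07,617.0479673552543,all,False,study012
Mycobacterium_leprae,6.010083436023097e-08,123.74871671416915,all,False,study013
Mycobacterium_leprae,4.5924114889848436e-08,441.462239698483,all,False,study014
Mycobacterium_tuberculosis,5.1354376524923665e-06,1.0,all,False,study015
Mycobacterium_tuberculosis,5.96847890363704e-06,2.102645968868926,all,False,study016
Mycobacterium_tuberculosis,1.4614651596405461e-05,1.0180268582003253,all,False,study017
Mycobacterium_tuberculosis,1.965707566232151e-06,3.4174580505802252,all,False,study018
Salmonella_enterica,1.1955843706650918e-05,34.954736997200385,all,False,study019
Salmonella_enterica,5.509710372968524e-06,8.791827723733693,all,False,study020
Salmonella_enterica,1.1028767283470934e-05,13.58675868629857,all,False,study021
Salmonella_enterica,3.7672983481839335e-06,32.75334512209204,all,False,study022
Staphylococcus_aureus,2.804954589517679e-06,1449.9999999999998,all,False,study023
Staphylococcus_aureus,5.094164358448928e-06,555.1481226629422,all,False,study024
Staphylococcus_aureus,1.0834251602128696e-06,104.45678106266688,all,False,study025
Staphylococcus_aureus,8.195887542599091e-07,45.16247475799106,all,False,study026
Streptococcus_pneumoniae,9.404867448353246e-07,734.610251814198,all,False,study027
Streptococcus_pneumoniae,1.2719559793756385e-06,9.385098564549871,all,False,study028
Streptococcus_pneumoniae,1.751749757302776e-06,1449.9999999999998,all,False,study029
Streptococcus_pneumoniae,1.4742279060312532e-06,4.509318100128736,all,False,study030
Streptococcus_pneumoniae,4.3383479385726085e-07,1449.9999999999998,all,False,study031
Vibrio_cholerae,2.3280198681146714e-06,5.910984505500441,all,False,study032
Vibrio_cholerae,1.0142578675891401e-06,1335.6365086413427,all,False,study033
Vibrio_cholerae,5.999867992534917e-07,66.6280635464365,all,False,study034
Vibrio_cholerae,2.4820004400395073e-06,701.4837886398419,all,False,study035
Vibrio_cholerae,7.037296118677912e-07,13.945232957158783,all,False,study036
Yersinia_pestis,9.62703704090195e-08,335.91035354934615,all,False,study037
Yersinia_pestis,2.724507629625941e-07,17.72824380683405,all,False,study038
Yersinia_pestis,2.571784571873164e-07,1178.4346382515841,all,False,study039
Yersinia_pestis,2.201014085862178e-07,1449.9999999999998,all,False,study040
Yersinia_pestis,2.321835763053236e-07,1449.9999999999998,all,False,study041
Yersinia_pestis,1.3357047174799e-07,1449.9999999999998,all,False,study042
Acinetobacter_baumannii,3.5452219565600536e-07,1449.9999999999998,all,False,study043
Bacillus_anthracis,2.813663794100062e-06,15.797192587556632,all,False,study044
Bordetella_pertussis,1.6850451795126557e-06,1449.9999999999998,all,False,study045
Borrelia_burgdorferi,3.070882587367778e-07,14.916464604383346,all,False,study046
Brucella_abortus,1.6789692373020982e-06,1207.783652336994,all,False,study047
Burkholderia_pseudomallei,9.356685161274326e-07,3.527127731746774,all,False,study048
Chlamydia_trachomatis,3.2101231203517186e-06,46.13151159701425,all,False,study049
Enterococcus_faecium,7.324219919656084e-06,117.84438666496044,all,False,study050
Francisella_tularensis,1.7724371802044273e-06,9.500549745552338,all,False,study051
Haemophilus_influenzae,1.9289239442616983e-05,87.6040932680091,all,False,study052
Klebsiella_pneumoniae,3.0952804243812207e-06,1449.9999999999998,all,False,study053
Klebsiella_pneumoniae,3.3788222023073343e-07,118.69653235382505,all,False,study054
Klebsiella_pneumoniae,1.668449193510467e-06,1031.6769677741174,all,False,study055
Klebsiella_pneumoniae,1.6008169078158522e-06,40.776258194615664,all,False,study056
Klebsiella_pneumoniae,1.4794594559229188e-06,2.8581025776052384,all,False,study057
Klebsiella_pneumoniae,4.3315733946139746e-07,43.51019738856657,all,False,study058
Legionella_pneumophila,1.0232295646507878e-06,1.0,all,False,study059
Leptospira_interrogans,2.950465104086183e-06,1.0,all,False,study060
Listeria_monocytogenes,1.1042586018002503e-06,6.677960185612985,all,False,study061
Moraxella_catarrhalis,2.061368488620988e-06,1449.9999999999998,all,False,study062
Neisseria_gonorrhoeae,1.928743612105951e-06,1449.9999999999998,all,False,study063
Neisseria_meningitidis,5.941621494880238e-07,26.857790352527783,all,False,study064
Pseudomonas_aeruginosa,4.070647544127315e-06,27.985760517540925,all,False,study065
Shigella_sonnei,9.406492509160582e-07,887.7337481314929,all,False,study066
Streptococcus_pyogenes,3.6285456335929513e-06,9.066309314000003,all,False,study067
Treponema_pallidum,4.171198027249604e-06,750.8272265191024,all,False,study068
Xanthomonas_oryzae,8.662505684224893e-06,6.82195391092132,all,False,study069
Escherichia_coli,3.467858152530784e-05,10.0,all,True,excl_hyper1
Staphylococcus_aureus,1.1346975397722303e-05,5.0,all,True,excl_hyper2
Helicobacter_pylori,4.770878715143054e-07,25.0,synonymous,False,excl_syn1
Mycobacterium_leprae,1.9952623149688786e-08,2000.0,all,False,excl_time1
Yersinia_pestis,3.981071705534969e-08,4500.0,all,False,excl_time2
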