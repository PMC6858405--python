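(('Chlamydia_trachomatis':2.3310066339120286,('Helicobacter_pylori':1.985700110266702,((((('Klebsiella_pneumoniae':0.9808907910979214,((('Enterococcus_faecium':0.022981849821711364,'Streptococcus_pneumoniae':0.022981849821711364):0.4475440403852442,'Moraxella_catarrhalis':0.47052589020695557):0.09377759867729019,'Treponema_pallidum':0.5643034888842458):0.4165873022136757):0.4489149867408537,(((('Burkholderia_pseudomallei':0.07121025309864226,'Francisella_tularensis':0.07121025309864226):0.4116239434754654,'Acinetobacter_baumannii':0.48283419657410764):0.1842441159991548,'Mycobacterium_tuberculosis':0.6670783125732624):0.5624939985509796,'Xanthomonas_oryzae':1.229572311124242):0.20023346671453313):0.11069873425312426,(('Shigella_sonnei':0.5081500299298014,('Escherichia_coli':0.3061575609448264,'Brucella_abortus':0.3061575609448264):0.20199246898497503):0.6802251856555004,'Leptospira_interrogans':1.1883752155853018):0.35212929650659763):0.00913076852352468,('Buchnera_aphidicola':1.4635089054290877,'Listeria_monocytogenes':1.4635089054290877):0.08612637518633637):0.3014474295063141,((('Haemophilus_influenzae':0.8777366313869193,'Mycobacterium_leprae':0.8777366313869193):0.431814224511903,('Neisseria_meningitidis':0.8518524251635369,(('Pseudomonas_aeruginosa':0.37612940507615367,('Bacillus_anthracis':0.22739226055355743,('Neisseria_gonorrhoeae':0.12493287045118517,'Salmonella_enterica':0.12493287045118517):0.10245939010237226):0.14873714452259623):0.4576733122983354,('Campylobacter_jejuni':0.8248400867208812,'Legionella_pneumophila':0.8248400867208812):0.008962630653607917):0.018049707789047797):0.4576984307352854):0.37825460135299993,('Clostridioides_difficile':0.553728300023054,('Borrelia_burgdorferi':0.40863102853875155,('Yersinia_pestis':0.3973941968193557,'Staphylococcus_aureus':0.3973941968193557):0.011236831719395823):0.1450972714843024):1.1340771572287682):0.163277252869916):0.13461740014496382):0.34530652364532655):0.29908840935917924,(('Streptococcus_pyogenes':0.12221361382850215,'Bordetella_pertussis':0.12221361382850215):0.7234327365737032,'Vibrio_cholerae':0.8456463504022054):1.7844486928690024):0.0;
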