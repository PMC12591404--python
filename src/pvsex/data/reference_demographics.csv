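drug,block,category,count
NRT,sex,Female,11935
NRT,sex,Male,6673
NRT,sex,Other,5
NRT,sex,Unknown,511
NRT,age,<25,988
NRT,age,25-40,4805
NRT,age,40-55,7314
NRT,age,>55,6017
NRT,country,United States,16745
NRT,country,United Kingdom,233
NRT,country,Canada,201
NRT,country,Japan,73
NRT,country,Other countries,1639
NRT,country,Unknown,233
NRT,outcome,Death,105
NRT,outcome,Life-threatening event,55
NRT,outcome,Hospitalization,423
NRT,outcome,Disability,33
NRT,outcome,Required intervention,27
NRT,outcome,Other adverse events,1960
NRT,outcome,Unknown,16521
Varenicline,sex,Female,12690
Varenicline,sex,Male,8262
Varenicline,sex,Other,14
Varenicline,sex,Unknown,532
Varenicline,age,<25,540
Varenicline,age,25-40,5000
Varenicline,age,40-55,9883
Varenicline,age,>55,6075
Varenicline,country,United States,20055
Varenicline,country,United Kingdom,279
Varenicline,country,Canada,241
Varenicline,country,Japan,86
Varenicline,country,Other countries,651
Varenicline,country,Unknown,186
Varenicline,outcome,Death,520
Varenicline,outcome,Life-threatening event,619
Varenicline,outcome,Hospitalization,2032
Varenicline,outcome,Disability,387
Varenicline,outcome,Required intervention,144
Varenicline,outcome,Other adverse events,5830
Varenicline,outcome,Unknown,11966
Bupropion,sex,Female,8818
Bupropion,sex,Male,4553
Bupropion,sex,Other,16
Bupropion,sex,Unknown,294
Bupropion,age,<25,1459
Bupropion,age,25-40,4798
Bupropion,age,40-55,5265
Bupropion,age,>55,2159
Bupropion,country,United States,12770
Bupropion,country,United Kingdom,127
Bupropion,country,Canada,153
Bupropion,country,Japan,55
Bupropion,country,Other countries,430
Bupropion,country,Unknown,146
Bupropion,outcome,Death,2539
Bupropion,outcome,Life-threatening event,720
Bupropion,outcome,Hospitalization,1915
Bupropion,outcome,Disability,275
Bupropion,outcome,Required intervention,153
Bupropion,outcome,Other adverse events,3307
Bupropion,outcome,Unknown,4772
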