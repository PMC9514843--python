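country,census_year,mother_ethnicity,mother_birth_country,birth_order,prior_sons,prior_daughters,males,females,published_csr
Australia,2001,Indian,India,2,0,1,1267,1129,891
Australia,2001,Indian,India,3,0,2,155,116,748
Australia,2001,Chinese,China,2,0,1,2017,1889,937
Australia,2001,Chinese,China,3,0,2,214,181,846
Australia,2006,Indian,India,2,0,1,1592,1399,879
Australia,2006,Indian,India,3,0,2,167,127,760
Australia,2006,Chinese,China,2,0,1,2428,2341,964
Australia,2006,Chinese,China,3,0,2,241,212,880
Australia,2011,Indian,India,2,0,1,3061,2680,876
Australia,2011,Indian,India,3,0,2,261,201,770
Australia,2011,Chinese,China,2,0,1,2904,2731,940
Australia,2011,Chinese,China,3,0,2,282,252,894
Australia,2016,Indian,India,2,0,1,7419,6590,888
Australia,2016,Indian,India,3,0,2,596,389,653
Australia,2016,Chinese,China,2,0,1,5271,4664,885
Australia,2016,Chinese,China,3,0,2,421,334,793
Canada,2001,Indian,India,2,0,1,618,531,859
Canada,2001,Indian,India,3,0,2,137,74,540
Canada,2001,Chinese,China,2,0,1,451,463,1027
Canada,2001,Chinese,China,3,0,2,62,56,903
Canada,2016,Indian,India,2,0,1,12275,10825,882
Canada,2016,Indian,India,3,0,2,2085,1085,520
Canada,2016,Chinese,China,2,0,1,8370,7855,938
Canada,2016,Chinese,China,3,0,2,810,710,877
UK,2001,Indian,India,2,0,1,6049,5515,912
UK,2001,Indian,India,3,0,2,1192,1009,846
UK,2001,Chinese,China,2,0,1,465,424,912
UK,2001,Chinese,China,3,0,2,60,47,783
UK,2011,Indian,India,2,0,1,8378,7730,923
UK,2011,Indian,India,3,0,2,1280,996,778
UK,2011,Chinese,China,2,0,1,1366,1263,925
UK,2011,Chinese,China,3,0,2,179,173,966
US,2000,Indian,India,2,0,1,930,815,876
US,2000,Indian,India,3,0,2,182,100,549
US,2000,Chinese,China,2,0,1,710,553,779
US,2000,Chinese,China,3,0,2,109,83,761
US,2004,Indian,India,2,0,1,398,362,910
US,2004,Indian,India,3,0,2,68,42,618
US,2004,Chinese,China,2,0,1,292,274,938
US,2004,Chinese,China,3,0,2,42,42,
US,2009,Indian,India,2,0,1,1613,1521,943
US,2009,Indian,India,3,0,2,244,139,570
US,2009,Chinese,China,2,0,1,1105,1094,990
US,2009,Chinese,China,3,0,2,173,135,780
US,2014,Indian,India,2,0,1,1997,1947,975
US,2014,Indian,India,3,0,2,274,163,595
US,2014,Chinese,China,2,0,1,1374,1250,910
US,2014,Chinese,China,3,0,2,212,156,736
US,2019,Indian,India,2,0,1,2650,2381,898
US,2019,Indian,India,3,0,2,210,169,805
US,2019,Chinese,China,2,0,1,1640,1524,929
US,2019,Chinese,China,3,0,2,238,186,782
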