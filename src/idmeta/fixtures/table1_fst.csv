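common_name,species,manual_group,kmeans_group_published,reference,fst,marker_type,n_markers,n_pops,region
Norway spruce,Picea abies,1,1,Unger et al. (2012),0.002,EST-SSR,6,3,Austria
Norway spruce,Picea abies,1,1,Achere et al. (2005),0.009,ncSSR,25,3,Europe
Norway spruce,Picea abies,1,1,Achere et al. (2005),0.029,AFLP,265,3,Europe
Norway spruce,Picea abies,1,1,Chen et al. (2012),0.05,SNP,445,18,Europe
Western white pine,Pinus monticola,2,2,Kim et al. (2011),0.201,AFLP,66,15,Western NA
Western white pine,Pinus monticola,2,2,Liu et al. (2011),0.163,SNP,53,7,Western NA
White spruce,Picea glauca,1,1,Namroud et al. (2008),0.006,SNP,534,6,Quebec
Maritime pine,Pinus pinaster,2,2,Wahid et al. (2010),0.120,ncSSR,7,10,Marocco
Maritime pine,Pinus pinaster,2,2,Soto et al. (2010),0.221,cpSSR,6,38,Iberia
Maritime pine,Pinus pinaster,2,2,Eveno et al. (2008),0.150,ncSSR,8,10,Mediterranean coast
Maritime pine,Pinus pinaster,2,2,Eveno et al. (2008),0.137,SNP,302,10,Mediterranean coast
Maritime pine,Pinus pinaster,2,2,Jaramillo-Correa et al. (2015),0.251,SNP,18,36,Mediterranean
European Larch,Larix decidua,2,1,Wagner et al. (2012),0.082,ncSSR,13,18,Central Europe
European Larch,Larix decidua,2,1,Mosca et al. (2012),0.043,SNP,267,24,Northern Italy
Scots pine,Pinus sylvestris,1,1,Soto et al. (2010),0.070,cpSSR,6,30,Iberia
Scots pine,Pinus sylvestris,1,1,Scalfi et al. (2009),0.080,ncSSR,3,3,Italy
Scots pine,Pinus sylvestris,1,1,Kahru et al. (1996),0.020,other,,,
Scots pine,Pinus sylvestris,1,1,Dvornyk et al. (2002),0.017,SNP,12,3,Finland and Russia
Scots pine,Pinus sylvestris,1,1,Dvornyk et al. (2002),0.11,SNP,12,4,"Finland, Russia and Spain"
Scots pine,Pinus sylvestris,1,1,Pyhajarvi et al. (2007),0.065,SNP,15,34,Europe
Loblolly pine,Pinus taeda,1,1,Eckert et al. (2010),0.043,SNP,1730,54,South east USA
Slash pine,Pinus elliottii,1,1,Berg and Hamrick (1997),0.028,Isozyme/Allozyme,21,6,South east USA
Radiata pine,Pinus radiata,2,2,Kahru et al. (2006),0.140,ncSSR,19,5,California
Radiata pine,Pinus radiata,2,2,Moran et al. (1988),0.162,Isozyme/Allozyme,31,5,California
Black pine,Pinus nigra,2,2,Soto et al. (2010),0.136,cpSSR,6,14,Iberia
P. pinceana,Pinus pinceana,2,2,Leidig et al. (2001),0.152,Isozyme/Allozyme,27,8,Mexico
Jack pine,Pinus banksiana,2,1,Saenz-Romero et al. (2001),0.022,Isozyme/Allozyme,82,14,Wisconsin
Jack pine,Pinus banksiana,2,1,Ye et al. (2002),0.155,RAPD,39,9,Alberta
Douglas fir,Pseudotsuga menziesii,1,1,Viard et al. (2001),0.019,cpSSR,11,11,British Columbia
Douglas fir,Pseudotsuga menziesii,1,1,Viard et al. (2001),0.072,RAPD,48,,British Columbia
Douglas fir,Pseudotsuga menziesii,1,1,Viard et al. (2001),0.018,Isozyme/Allozyme,20,,British Columbia
Nobel fir,Abies procera,2,2,Yeh and Hu (2005),0.112,Isozyme/Allozyme,14,21,Oregon to Washington
Ponderosa pine,Pinus ponderosa,2,2,Latta & Mitton (1999),0.062,Isozyme/Allozyme,15,8,western North America
Ponderosa pine,Pinus ponderosa,2,2,Latta & Mitton (1999),1.000,RAPD,4,,western North America
Ponderosa pine,Pinus ponderosa,2,2,Latta & Mitton (1999),0.652,RAPD,3,,western North America
Lodgepole pine,Pinus contorta,1,1,Parchman et al. (2012),0.008,SNP,97616,3,Wyoming
Virginia pine,Pinus virginiana,1,1,Parker et al. (1997),0.053,Isozyme/Allozyme,26,19,Eastern USA
Blue spruce,Picea pungens,2,1,Leidig et al. (2006),0.086,Isozyme/Allozyme,17,4,Western USA
Serbian spruce,Picea omorica,2,2,Ballian et al. (2006),0.261,Isozyme/Allozyme,16,13,Balkan
Black spruce,Picea mariana,1,1,Wang and Macdonald (1992),0.010,Isozyme/Allozyme,28,6,Canada
Silver fir,Abies alba,1,,Matusova (1995),0.015,Isozyme/Allozyme,15,5,Bulgaria
Silver fir,Abies alba,1,,Mosca et al. (2012),0.037,SNP,249,37,"Italy, Macedonia"
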