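compound_class,ri,match_score,cas,name,occ_kaalae,occ_hookeri,mean_nonzero_kaalae,mean_nonzero_hookeri,mean_kaalae,mean_hookeri,rel_kaalae_pct,rel_hookeri_pct,excluded
aliphatic,796,0.87,4440-65-7,(E)-hex-3-enal,0.00,0.50,,0.56,,0.28,,3.4,False
aliphatic,797,0.94,66-25-1,hexanal,1.00,1.00,0.56,0.80,0.56,0.80,3.4,9.5,False
aliphatic,830,0.90,96-04-8,"heptane-2,3-dione",0.08,0.86,0.05,0.54,0.00,0.46,0.0,5.6,False
aliphatic,840,0.91,6728-26-3,(E)-hex-2-enal,0.00,0.81,,0.43,,0.35,,4.2,False
aliphatic,848,0.94,928-96-1,(Z)-hex-3-en-1-ol,0.21,0.89,0.24,6.64,,,,,True
aliphatic,855,0.78,7642-10-6,hept-3-ene,0.05,0.22,0.24,0.26,0.01,0.06,0.1,0.7,False
aliphatic,855,0.84,4412-91-3,furan-3-ylmethanol,0.08,0.25,0.10,0.95,0.01,0.24,0.0,2.8,False
aliphatic,855,0.89,2415-72-7,propylcyclopropane,0.32,0.25,0.08,0.33,0.03,0.08,0.2,1.0,False
aliphatic,882,0.84,2216-34-4,4-methyloctane,0.21,0.03,0.03,0.01,0.01,0.00,0.0,0.0,False
aliphatic,901,0.92,13129-23-2,methyl furan-3-carboxylate,0.00,0.33,,0.03,,0.01,,0.1,False
aliphatic,905,0.92,3008-40-0,"cyclopentane-1,2-dione",0.21,0.22,0.78,1.85,0.16,0.41,1.0,4.9,False
aliphatic,933,0.83,18829-55-5,hept-2-enal,0.37,0.00,0.06,,0.02,,0.1,,False
aliphatic,949,0.79,26456-76-8,"3,5,5-trimethylhex-2-ene",0.05,0.47,0.05,0.40,0.00,0.19,0.0,2.3,False
aliphatic,960,0.92,3391-86-4,oct-1-en-3-ol,1.00,1.00,3.17,3.38,3.17,3.38,19.3,40.6,False
aliphatic,961,0.92,106-68-3,octan-3-one,0.89,0.97,0.49,0.72,0.44,0.70,2.7,8.4,False
aliphatic,971,0.84,111-13-7,octan-2-one,0.21,0.00,0.04,,0.01,,0.0,,False
aliphatic,981,0.92,72237-36-6,hex-4-enyl acetate,0.00,0.25,,0.35,,0.09,,1.1,False
aliphatic,1152,0.87,53398-84-8,[(E)-hex-3-enyl] butanoate,0.00,0.28,,0.29,,0.08,,1.0,False
aliphatic,1347,0.90,31501-11-8,[(Z)-hex-3-enyl] hexanoate,0.00,0.28,,0.27,,0.07,,0.9,False
benzenoid,896,0.91,100-66-3,anisole,0.03,0.39,0.01,0.02,0.00,0.01,0.0,0.1,False
benzenoid,937,0.95,100-52-7,benzaldehyde,1.00,1.00,0.07,0.30,0.07,0.30,0.5,3.7,False
benzenoid,1017,0.92,122-78-1,2-phenylacetaldehyde,0.95,0.50,0.29,0.01,0.27,0.01,1.7,0.1,False
benzenoid,1179,,,unknown benzenoid,0.11,0.64,0.02,0.42,0.00,0.27,0.0,3.2,False
benzenoid,1198,0.86,103-70-8,N-phenylformamide,0.00,0.25,,0.09,,0.02,,0.3,False
benzenoid,1268,0.92,120-72-9,indole,0.13,0.89,0.02,0.16,0.00,0.15,0.0,1.8,False
benzenoid,1316,0.94,134-20-3,methyl 2-aminobenzoate,0.05,0.61,0.00,0.14,0.00,0.08,0.0,1.0,False
irregular terpene,1086,0.82,19945-61-0,"(3E)-4,8-dimethylnona-1,3,7-triene",0.03,0.64,0.05,0.15,0.00,0.09,0.0,1.1,False
irregular terpene,1115,0.90,1125-21-9,4-oxoisophorone,1.00,0.03,0.13,0.00,0.13,0.00,0.8,0.0,False
irregular terpene,1120,0.87,28564-83-2,"3,5-dihydroxy-6-methyl-2,3-dihydropyran-4-one",0.16,0.22,0.14,0.13,0.02,0.03,0.1,0.3,False
irregular terpene,1139,0.87,20547-99-3,"2,2,6-trimethylcyclohexane-1,4-dione",0.84,0.00,0.06,,0.05,,0.3,,False
irregular terpene,1322,0.81,141891-14-7,"4-hydroxy-2,6,6-trimethyl-3-oxocyclohexene-1-carbaldehyde",0.71,0.03,0.04,0.04,0.03,0.00,0.2,0.0,False
monoterpene,964,0.84,123-35-3,beta-myrcene,0.47,0.03,0.02,0.02,0.01,0.00,0.1,0.0,False
monoterpene,978,0.90,99-83-2,alpha-phellandrene,0.76,0.42,0.46,0.04,0.35,0.02,2.2,0.2,False
monoterpene,997,0.89,99-87-6,p-cymene,0.55,0.22,0.12,0.06,0.07,0.01,0.4,0.2,False
monoterpene,1013,0.85,3779-61-1,(E)-beta-ocimene,0.26,0.00,0.02,,0.00,,0.0,,False
monoterpene,1061,0.94,5989-33-3,linalool oxide (furanoid),1.00,0.22,2.13,0.08,2.13,0.02,13.0,0.2,False
monoterpene,1071,0.82,78-70-6,linalool,0.34,0.47,0.11,0.05,0.04,0.03,0.2,0.3,False
monoterpene,1087,0.93,33933-72-1,linalool oxide (pyranoid) ketone,1.00,0.75,4.82,0.11,4.82,0.08,29.4,1.0,False
monoterpene,1152,0.93,39028-58-5,linalool oxide (pyranoid),1.00,0.22,3.98,0.10,3.98,0.02,24.2,0.3,False
monoterpene,1245,0.78,EPA-7965,epoxy-linalooloxide,0.39,0.00,0.04,,0.02,,0.1,,False
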