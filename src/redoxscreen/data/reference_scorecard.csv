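# Reference scorecard: component scores and rank labels of the 18 ranked
# migration-enhancing, ROS-reducing compounds from the melanoma redox
# screen this pipeline models.  Shipped to validate scorecard arithmetic
# and dense ranking; the GSH row's printed total (26) does not equal the
# sum of its printed components (22) and is carried as printed.
rank,common_name,other_name,migration_max16,ros_max16,dose_response_max32,total_max64
1,Vitamin C,Ascorbic acid,14,9,19,42
2,Vitamin E,Trolox,14,10,17,41
3,Protocatechuic acid,"3,4-Dihydroxybenzoic acid",13,14,13,40
3,Probucol,"Lorelco, Biphenabid",14,10,16,40
4,β-Carotene,Provitamin A,9,8,12,29
5,D609,Tricyclodecan-9-yl-xanthogenate,12,9,6,27
6,GSH,Glutathione,10,6,6,26
7,Canthaxanthin,"β-Carotin-4,4′-dione",11,7,6,24
8,Seratrodast,"(±)-7-(3,5,6-Trimethyl-1,4-benzoquinon-2-yl)-7-phenylheptanoic acid",9,5,3,17
9,Cumene hydroperoxide,"α,α-Dimethylbenzyl hydroperoxide",13,1,0,14
9,Selenomethionine,"Seleno-L-methionine, (S)-2-Amino-4-(methylseleno)butyric acid",9,5,0,14
9,Tert-butylhydroquinone,NSC 4972,7,7,0,14
10,Paeonol,Resacetophenone 4-O-methyl ether,4,9,0,13
10,Ferulic acid,4-Hydroxy-3-methoxycinnamic acid,6,7,0,13
11,Ibuproxam,N-Hydroxy-2-(4-isobutylphenyl)propanamid,4,8,0,12
11,Esculetin,Cichorigenin,7,5,0,12
12,Retinyl palmitate,Vitamin A palmitate,5,5,0,10
12,Ibedenone,"2-(10-Hydroxydecyl)-5,6-dimethoxy-3-methyl-1,4-benzoquinone",6,4,0,10
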