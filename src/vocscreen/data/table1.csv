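compound_id,name,cas,formula,class,A.1,A.2,A.3,A.4,A.5
1,α-Pinene,7785-70-8,C10H16,MONOTERPENE,22.6%,ND,ND,ND,ND
2,3-Carene,13466-78-9,C10H16,MONOTERPENE,11.0%,34.8%,46.5%,49.9%,55.2%
3,Camphene,79-92-5,C10H16,MONOTERPENE,ND,ND,0.5%,0.6%,0.5%
4,α-Campholenal,4501-58-0,C10H16O,MONOTERPENE,ND,7.7%,ND,4.6%,ND
5,"Camphenol,6-",3570-04-5,C10H16O,MONOTERPENE,14.9%,ND,4.2%,ND,5.7%
6,D-Limonene,5989-27-5,C10H16,MONOTERPENE,ND,23.0%,ND,ND,ND
7,"m-Mentha-6,8-diene",1461-27-4,C10H16,MONOTERPENE,ND,ND,30.7%,ND,ND
8,"p-Mentha-1,4(8)-diene",586-62-9,C10H16,MONOTERPENE,1.0%,1.3%,0.9%,2.9%,ND
9,"p-1,8-diene,(S)",5989-54-8,C10H16,MONOTERPENE,5%,ND,ND,10.4%,21.1%
10,β-Guaiene,88-84-6,C15H24,SESQUITERPENE,,0.8%,,,0.2%
11,Caryophyllene,87-44-5,C15H24,SESQUITERPENE,11.4%,6.0%,1.9%,0.6%,0.3%
12,Cedr-8(15)-ene,11028-42-5,C15H24,SESQUITERPENE,1.7%,1.2%,0.6%,2.6%,ND
13,Elemene,339154-9,C15H24,SESQUITERPENE,0.2%,ND,ND,ND,ND
14,β-Chamigrene,18431-82-8,C15H24,SESQUITERPENE,ND,ND,ND,ND,0.4%
15,"Guaia-1(5),11-diene",3691-12-1,C15H24,SESQUITERPENE,ND,ND,0.4%,ND,ND
16,Patchoulene,1405-16-9,C15H24,SESQUITERPENE,ND,0.6%,ND,ND,ND
17,"1H-Benzocycloheptene,2,4aα,5,6,7,8,9aα-octahydro-3,5,5-trimethyl-9-methylene-",3853-83-6,C15H24,SESQUITERPENE,1%,0.8%,ND,0.8%,ND
18,Ethylcaproate,123-66-0,C8H16O2,OTHER,4.0%,ND,0.8%,ND,ND
19,cis-Geranylacetone,3879-26-3,C13H22O,OTHER,27.2%,ND,25.4%,24.3%,10.3%
20,"o-Anisic acid, methylester",606-45-1,C9H10O3,OTHER,ND,0.5%,ND,ND,0.7%
21,"Salicylic acid, methyl, methylester",119-36-8,C8H8O3,OTHER,ND,2.3%,ND,2.0%,5.6%
22,trans-Geranylacetone,3796-70-1,C13H22O,OTHER,ND,21.6%,ND,ND,ND
23,Hexanoic acid 1-cyclopentylethylester,NA,C13H24O2,OTHER,ND,ND,ND,0.6%,ND
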