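ranking,journal,papers,ratio_pct
1,Biochemistry,62270,25.78
2,Journal of Molecular Biology,29968,12.41
3,The EMBO Journal,17296,7.16
4,Journal of Theoretical Biology,12200,5.05
5,Bioinformatics,9847,4.08
6,Human Molecular Genetics,9347,3.87
7,Genomics,8316,3.44
8,BMC Genomics,7741,3.2
9,BMC Bioinformatics,6780,2.81
10,Protein Science : a publication of the Protein Society,6047,2.5
11,Journal of Proteome Research,5575,2.31
12,Proteomics,5545,2.3
13,Journal of Biotechnology,5204,2.15
14,PLOS Genetics,5139,2.13
15,PLOS Computational Biology,3852,1.59
16,BMC Research Notes,3743,1.55
17,Mammalian Genome,3499,1.45
18,Genome Biology,3411,1.41
19,PLOS Biology,3280,1.36
20,Trends in Biochemical Sciences,3171,1.31
21,Trends in Genetics,3035,1.26
22,Journal of Molecular Modeling,2852,1.18
23,Molecular & cellular proteomics : MCP,2796,1.16
24,Trends in Biotechnology,2353,0.97
25,Bulletin of Mathematical Biology,2331,0.96
26,Journal of Proteomics,2158,0.89
27,Physiological Genomics,1794,0.74
28,Journal of Computer-Aided Molecular Design,1706,0.71
29,BMC Systems Biology,1397,0.58
30,Bioinformation,1297,0.54
31,Pharmacogenetics and Genomics,1072,0.44
32,Statistical Methods in Medical Research,976,0.4
33,Journal of Computational Neuroscience,925,0.38
34,Molecular Systems Biology,822,0.34
35,Genome Medicine,676,0.28
36,Theoretical Biology and Medical Modeling,498,0.21
37,Comparative and Functional Genomics,466,0.19
38,Neuroinformatics,385,0.16
39,Cancer Informatics,355,0.15
40,Briefings in Functional Genomics & Proteomics,290,0.12
41,Evolutionary Bioinformatics,249,0.1
42,Algorithms for Molecular Biology,245,0.1
43,Journal of Biomedical Semantics,240,0.1
44,BioData Mining,149,0.06
45,EURASIP Journal on Bioinformatics and Systems Biology,140,0.06
46,Source Code for Biology and Medicine,131,0.05
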