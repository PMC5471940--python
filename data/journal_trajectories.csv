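journal,sum_probability,average_probability
Biochemistry,13.13233,3.28308
"Bioinformatics (Oxford, England)",2.49214,0.62304
BMC Bioinformatics,1.64624,0.41156
BMC Genomics,1.92022,0.48005
Bulletin of mathematical biology,0.68576,0.17144
Genome biology,1.2869,0.32173
Genomics,2.40453,0.60113
Human molecular genetics,2.98031,0.74508
Journal of biotechnology,1.32392,0.33098
Journal of computational neuroscience,0.42877,0.10719
Journal of computer-aided molecular design,0.60322,0.15081
Journal of molecular biology,5.82534,1.45633
Journal of theoretical biology,3.0082,0.75205
Mammalian genome,1.06714,0.26678
Physiological genomics,0.61599,0.154
Protein science,2.16372,0.54093
Statistical methods in medical research,0.25062,0.06266
The EMBO journal,3.35207,0.83802
Trends in biochemical sciences,0.50571,0.12643
Trends in biotechnology,0.50871,0.12718
Trends in genetics,0.73352,0.18338
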