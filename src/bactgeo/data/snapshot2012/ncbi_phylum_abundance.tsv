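# December-2012 NCBI Nucleotide snapshot: records assigned to each of the
# 24 harmonized phyla (Ab), summed over the 208-area study frame.
phylum	ab
Acidobacteria	15043
Actinobacteria	106127
Aquificae	1417
Bacteroidetes	35795
Chlamydiae	1489
Chlorobi	858
Chloroflexi	4762
Chrysiogenetes	9
Cyanobacteria	43896
Deferribacteres	152
Deinococcus-Thermus	710
Dictyoglomi	37
Fibrobacteres	821
Firmicutes	167616
Fusobacteria	375
Gemmatimonadetes	1819
Lentisphaerae	79
Nitrospirae	3118
Planctomycetes	9734
Proteobacteria	841254
Spirochaetes	59943
Thermodesulfobacteria	80
Thermotogae	381
Verrucomicrobia	15534
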