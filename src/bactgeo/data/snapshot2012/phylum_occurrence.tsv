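# December-2012 snapshots: number of study-frame areas (of 208) with at
# least one record of each phylum (Oc), per source database.
phylum	ncbi_oc	gbif_oc
Acidobacteria	55	42
Actinobacteria	144	124
Aquificae	20	14
Bacteroidetes	112	75
Chlamydiae	37	41
Chlorobi	32	35
Chloroflexi	62	44
Chrysiogenetes	5	1
Cyanobacteria	114	177
Deferribacteres	21	40
Deinococcus-Thermus	47	40
Dictyoglomi	6	2
Fibrobacteres	16	28
Firmicutes	139	112
Fusobacteria	26	40
Gemmatimonadetes	39	41
Lentisphaerae	14	41
Nitrospirae	40	41
Planctomycetes	64	46
Proteobacteria	189	173
Spirochaetes	92	47
Thermodesulfobacteria	9	8
Thermotogae	21	29
Verrucomicrobia	56	47
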