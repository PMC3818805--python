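# The 24 bacterial phyla shared between the NCBI Taxonomy and the
# Catalogue of Life classifications (the study's harmonized phylum frame).
Acidobacteria
Actinobacteria
Aquificae
Bacteroidetes
Chlamydiae
Chlorobi
Chloroflexi
Chrysiogenetes
Cyanobacteria
Deferribacteres
Deinococcus-Thermus
Dictyoglomi
Fibrobacteres
Firmicutes
Fusobacteria
Gemmatimonadetes
Lentisphaerae
Nitrospirae
Planctomycetes
Proteobacteria
Spirochaetes
Thermodesulfobacteria
Thermotogae
Verrucomicrobia
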