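# Classification-dialect synonym table: spelling used by a source
# classification -> canonical phylum of the 24-name frame.
# Editable; names absent here and from the frame stay "unassigned".
dialect_name	canonical
Pseudomonadota	Proteobacteria
Bacillota	Firmicutes
Actinomycetota	Actinobacteria
Bacteroidota	Bacteroidetes
Cyanophyta	Cyanobacteria
Spirochaetota	Spirochaetes
Verrucomicrobiota	Verrucomicrobia
Planctomycetota	Planctomycetes
Acidobacteriota	Acidobacteria
Chloroflexota	Chloroflexi
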