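# GBIF species-portal overview (March 2013): georeferenced records per kingdom.
kingdom	records
Archaea	26501
Bacteria	1593278
Animalia	238944036
Chromista	1539408
Fungi	6176944
Plantae	80044950
Protozoa	3916926
Incertae sedis	616822
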