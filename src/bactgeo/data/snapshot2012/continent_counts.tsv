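# December-2012 snapshots: matched and phylum-assigned records by continent.
continent	gbif_records	gbif_assigned	ncbi_records	ncbi_assigned
AMERICA	481976	421526	1200669	634225
AFRICA	42289	37972	55796	39723
EUROPE	335373	306014	371561	214725
ASIA	143984	126967	504874	341823
AUSTRALIA-OCEANIA	204615	182665	96073	72257
ANTARCTICA	13979	13363	93366	8296
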