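# Join aliases for map rendering: external name -> canonical area name.
alias	canonical
United States	USA
United States of America	USA
Great Britain	United Kingdom
Russian Federation	Russia
Vietnam	Viet Nam
Republic of Korea	South Korea
Ivory Coast	Cote d'Ivoire
DR Congo	Democratic Republic of Congo
Czechia	Czech Republic
Burma	Myanmar
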