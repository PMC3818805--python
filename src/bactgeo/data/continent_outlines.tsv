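# Schematic continent outlines (lon,lat vertex chains) for choropleth
# rendering. Deliberately coarse: shapes are recognisable silhouettes,
# not survey-grade boundaries.
continent	vertices
AMERICA	-170,68;-130,72;-90,72;-60,60;-55,48;-75,35;-80,25;-85,15;-75,5;-60,-5;-40,-10;-40,-25;-55,-40;-70,-55;-75,-40;-80,-20;-85,0;-95,15;-105,22;-120,35;-130,45;-165,58
EUROPE	-10,36;0,38;10,38;25,35;30,40;40,42;60,48;60,70;30,72;10,70;-5,58;-10,50
AFRICA	-17,15;-10,32;10,37;32,31;43,11;51,11;40,-5;35,-20;30,-34;18,-35;12,-18;8,0;-8,5
ASIA	60,48;40,42;35,36;45,25;55,22;60,25;70,20;78,8;80,15;90,22;100,8;105,0;110,5;110,20;122,25;122,40;135,45;140,50;160,60;178,65;178,72;100,78;60,70
AUSTRALIA-OCEANIA	113,-22;115,-35;130,-32;140,-38;148,-43;153,-30;150,-22;142,-11;135,-12;125,-14
ANTARCTICA	-178,-63;-90,-66;0,-63;90,-66;178,-63;178,-84;-178,-84
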