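# INSDC /country controlled-vocabulary study frame: 208 geographical areas, six continents.
# Columns: name<TAB>continent[<TAB>historical]
name	continent
Algeria	AFRICA
Angola	AFRICA
Benin	AFRICA
Botswana	AFRICA
Burkina Faso	AFRICA
Burundi	AFRICA
Cameroon	AFRICA
Cape Verde	AFRICA
Central African Republic	AFRICA
Chad	AFRICA
Comoros	AFRICA
Cote d'Ivoire	AFRICA
Democratic Republic of Congo	AFRICA
Djibouti	AFRICA
Egypt	AFRICA
Equatorial Guinea	AFRICA
Eritrea	AFRICA
Ethiopia	AFRICA
Gabon	AFRICA
Gambia	AFRICA
Ghana	AFRICA
Guinea	AFRICA
Guinea-Bissau	AFRICA
Kenya	AFRICA
Lesotho	AFRICA
Liberia	AFRICA
Libya	AFRICA
Madagascar	AFRICA
Malawi	AFRICA
Mali	AFRICA
Mauritania	AFRICA
Mauritius	AFRICA
Mayotte	AFRICA
Morocco	AFRICA
Mozambique	AFRICA
Namibia	AFRICA
Niger	AFRICA
Nigeria	AFRICA
Republic of the Congo	AFRICA
Reunion	AFRICA
Rwanda	AFRICA
Sao Tome and Principe	AFRICA
Senegal	AFRICA
Seychelles	AFRICA
Sierra Leone	AFRICA
Somalia	AFRICA
South Africa	AFRICA
Sudan	AFRICA
Tanzania	AFRICA
Togo	AFRICA
Tunisia	AFRICA
Uganda	AFRICA
Zambia	AFRICA
Zimbabwe	AFRICA
Albania	EUROPE
Andorra	EUROPE
Austria	EUROPE
Belarus	EUROPE
Belgium	EUROPE
Bosnia and Herzegovina	EUROPE
Bulgaria	EUROPE
Croatia	EUROPE
Cyprus	EUROPE
Czech Republic	EUROPE
Denmark	EUROPE
Estonia	EUROPE
Finland	EUROPE
France	EUROPE
Germany	EUROPE
Greece	EUROPE
Hungary	EUROPE
Iceland	EUROPE
Ireland	EUROPE
Italy	EUROPE
Latvia	EUROPE
Lithuania	EUROPE
Luxembourg	EUROPE
Macedonia	EUROPE
Malta	EUROPE
Moldova	EUROPE
Monaco	EUROPE
Montenegro	EUROPE
Netherlands	EUROPE
Norway	EUROPE
Poland	EUROPE
Portugal	EUROPE
Romania	EUROPE
Russia	EUROPE
Serbia	EUROPE
Slovakia	EUROPE
Slovenia	EUROPE
Spain	EUROPE
Svalbard	EUROPE
Sweden	EUROPE
Switzerland	EUROPE
Ukraine	EUROPE
United Kingdom	EUROPE
Afghanistan	ASIA
Armenia	ASIA
Azerbaijan	ASIA
Bangladesh	ASIA
Bhutan	ASIA
Brunei	ASIA
Cambodia	ASIA
China	ASIA
Georgia	ASIA
Hong Kong	ASIA
India	ASIA
Indonesia	ASIA
Iran	ASIA
Iraq	ASIA
Israel	ASIA
Japan	ASIA
Jordan	ASIA
Kazakhstan	ASIA
Kuwait	ASIA
Kyrgyzstan	ASIA
Laos	ASIA
Lebanon	ASIA
Malaysia	ASIA
Mongolia	ASIA
Myanmar	ASIA
Nepal	ASIA
North Korea	ASIA
Oman	ASIA
Pakistan	ASIA
Philippines	ASIA
Qatar	ASIA
Saudi Arabia	ASIA
Singapore	ASIA
South Korea	ASIA
Sri Lanka	ASIA
Syria	ASIA
Tajikistan	ASIA
Thailand	ASIA
Turkey	ASIA
Turkmenistan	ASIA
United Arab Emirates	ASIA
Uzbekistan	ASIA
Viet Nam	ASIA
Yemen	ASIA
Anguilla	AMERICA
Antigua and Barbuda	AMERICA
Argentina	AMERICA
Aruba	AMERICA
Bahamas	AMERICA
Barbados	AMERICA
Belize	AMERICA
Bermuda	AMERICA
Bolivia	AMERICA
Brazil	AMERICA
Canada	AMERICA
Cayman Islands	AMERICA
Chile	AMERICA
Colombia	AMERICA
Costa Rica	AMERICA
Cuba	AMERICA
Dominica	AMERICA
Dominican Republic	AMERICA
Ecuador	AMERICA
El Salvador	AMERICA
French Guiana	AMERICA
Greenland	AMERICA
Grenada	AMERICA
Guadeloupe	AMERICA
Guatemala	AMERICA
Guyana	AMERICA
Haiti	AMERICA
Honduras	AMERICA
Jamaica	AMERICA
Martinique	AMERICA
Mexico	AMERICA
Nicaragua	AMERICA
Panama	AMERICA
Paraguay	AMERICA
Peru	AMERICA
Puerto Rico	AMERICA
Saint Kitts and Nevis	AMERICA
Saint Lucia	AMERICA
Saint Vincent and the Grenadines	AMERICA
Suriname	AMERICA
Trinidad and Tobago	AMERICA
Uruguay	AMERICA
USA	AMERICA
Venezuela	AMERICA
Virgin Islands	AMERICA
American Samoa	AUSTRALIA-OCEANIA
Australia	AUSTRALIA-OCEANIA
Cook Islands	AUSTRALIA-OCEANIA
Fiji	AUSTRALIA-OCEANIA
French Polynesia	AUSTRALIA-OCEANIA
Guam	AUSTRALIA-OCEANIA
Kiribati	AUSTRALIA-OCEANIA
Marshall Islands	AUSTRALIA-OCEANIA
Micronesia	AUSTRALIA-OCEANIA
Nauru	AUSTRALIA-OCEANIA
New Caledonia	AUSTRALIA-OCEANIA
New Zealand	AUSTRALIA-OCEANIA
Niue	AUSTRALIA-OCEANIA
Northern Mariana Islands	AUSTRALIA-OCEANIA
Palau	AUSTRALIA-OCEANIA
Papua New Guinea	AUSTRALIA-OCEANIA
Samoa	AUSTRALIA-OCEANIA
Solomon Islands	AUSTRALIA-OCEANIA
Tonga	AUSTRALIA-OCEANIA
Tuvalu	AUSTRALIA-OCEANIA
Vanuatu	AUSTRALIA-OCEANIA
Antarctica	ANTARCTICA
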