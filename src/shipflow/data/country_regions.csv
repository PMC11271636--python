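country,region
Algeria,Northern Africa
Egypt,Northern Africa
Libya,Northern Africa
Morocco,Northern Africa
Sudan,Northern Africa
Tunisia,Northern Africa
Western Sahara,Northern Africa
Angola,Sub-Saharan Africa
Benin,Sub-Saharan Africa
Cabo Verde,Sub-Saharan Africa
Cameroon,Sub-Saharan Africa
Comoros,Sub-Saharan Africa
Congo,Sub-Saharan Africa
Cote d'Ivoire,Sub-Saharan Africa
Democratic Republic of the Congo,Sub-Saharan Africa
Djibouti,Sub-Saharan Africa
Equatorial Guinea,Sub-Saharan Africa
Eritrea,Sub-Saharan Africa
Gabon,Sub-Saharan Africa
Gambia,Sub-Saharan Africa
Ghana,Sub-Saharan Africa
Guinea,Sub-Saharan Africa
Guinea-Bissau,Sub-Saharan Africa
Kenya,Sub-Saharan Africa
Liberia,Sub-Saharan Africa
Madagascar,Sub-Saharan Africa
Mauritania,Sub-Saharan Africa
Mauritius,Sub-Saharan Africa
Mozambique,Sub-Saharan Africa
Namibia,Sub-Saharan Africa
Nigeria,Sub-Saharan Africa
Senegal,Sub-Saharan Africa
Seychelles,Sub-Saharan Africa
Sierra Leone,Sub-Saharan Africa
Somalia,Sub-Saharan Africa
South Africa,Sub-Saharan Africa
Tanzania,Sub-Saharan Africa
Togo,Sub-Saharan Africa
Bermuda,Northern America
Canada,Northern America
Greenland,Northern America
United States,Northern America
Belize,Central America
Costa Rica,Central America
El Salvador,Central America
Guatemala,Central America
Honduras,Central America
Mexico,Central America
Nicaragua,Central America
Panama,Central America
Antigua and Barbuda,Caribbean
Aruba,Caribbean
Bahamas,Caribbean
Barbados,Caribbean
Cayman Islands,Caribbean
Cuba,Caribbean
Curacao,Caribbean
Dominica,Caribbean
Dominican Republic,Caribbean
Grenada,Caribbean
Haiti,Caribbean
Jamaica,Caribbean
Puerto Rico,Caribbean
Saint Kitts and Nevis,Caribbean
Saint Lucia,Caribbean
Saint Vincent and the Grenadines,Caribbean
Trinidad and Tobago,Caribbean
Argentina,South America
Brazil,South America
Chile,South America
Colombia,South America
Ecuador,South America
French Guiana,South America
Guyana,South America
Peru,South America
Suriname,South America
Uruguay,South America
Venezuela,South America
Kazakhstan,Central Asia
Kyrgyzstan,Central Asia
Tajikistan,Central Asia
Turkmenistan,Central Asia
Uzbekistan,Central Asia
China,Eastern Asia
Hong Kong,Eastern Asia
Japan,Eastern Asia
Macao,Eastern Asia
Mongolia,Eastern Asia
North Korea,Eastern Asia
South Korea,Eastern Asia
Taiwan,Eastern Asia
Brunei,South-eastern Asia
Cambodia,South-eastern Asia
Indonesia,South-eastern Asia
Laos,South-eastern Asia
Malaysia,South-eastern Asia
Myanmar,South-eastern Asia
Philippines,South-eastern Asia
Singapore,South-eastern Asia
Thailand,South-eastern Asia
Timor-Leste,South-eastern Asia
Vietnam,South-eastern Asia
Bangladesh,Southern Asia
India,Southern Asia
Iran,Southern Asia
Maldives,Southern Asia
Pakistan,Southern Asia
Sri Lanka,Southern Asia
Bahrain,Western Asia
Cyprus,Western Asia
Georgia,Western Asia
Iraq,Western Asia
Israel,Western Asia
Jordan,Western Asia
Kuwait,Western Asia
Lebanon,Western Asia
Oman,Western Asia
Qatar,Western Asia
Saudi Arabia,Western Asia
Syria,Western Asia
Turkey,Western Asia
United Arab Emirates,Western Asia
Yemen,Western Asia
Belarus,Eastern Europe
Bulgaria,Eastern Europe
Czechia,Eastern Europe
Hungary,Eastern Europe
Moldova,Eastern Europe
Poland,Eastern Europe
Romania,Eastern Europe
Russia,Eastern Europe
Slovakia,Eastern Europe
Ukraine,Eastern Europe
Denmark,Northern Europe
Estonia,Northern Europe
Faroe Islands,Northern Europe
Finland,Northern Europe
Iceland,Northern Europe
Ireland,Northern Europe
Latvia,Northern Europe
Lithuania,Northern Europe
Norway,Northern Europe
Sweden,Northern Europe
United Kingdom,Northern Europe
Albania,Southern Europe
Croatia,Southern Europe
Gibraltar,Southern Europe
Greece,Southern Europe
Italy,Southern Europe
Malta,Southern Europe
Montenegro,Southern Europe
Portugal,Southern Europe
Slovenia,Southern Europe
Spain,Southern Europe
Belgium,Western Europe
France,Western Europe
Germany,Western Europe
Netherlands,Western Europe
Austria,Western Europe
Switzerland,Western Europe
Australia,Oceania
Fiji,Oceania
French Polynesia,Oceania
Kiribati,Oceania
Marshall Islands,Oceania
Micronesia,Oceania
Nauru,Oceania
New Caledonia,Oceania
New Zealand,Oceania
Palau,Oceania
Papua New Guinea,Oceania
Samoa,Oceania
Solomon Islands,Oceania
Tonga,Oceania
Tuvalu,Oceania
Vanuatu,Oceania
Antarctica,Antarctica
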