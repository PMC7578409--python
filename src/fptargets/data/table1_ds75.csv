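country,country_ascii,target_year,target_mcpr_pct,mcpr_gap_pp,users_gap_millions,acceleration,db_column_pct
Sri Lanka,Sri Lanka,2031,58.7,4.3,0.02,1.1,58.9
Ethiopia,Ethiopia,2032,53.0,15.3,6.35,1.2,52.1
Madagascar,Madagascar,2032,54.4,12.7,1.27,1.2,54.0
India,India,2036,57.2,7.3,27.74,1.5,56.7
Nepal,Nepal,2040,59.3,12.9,1.44,1.9,58.8
United Republic of Tanzania,United Republic of Tanzania,2040,55.5,18.1,3.0,1.9,52.9
Uganda,Uganda,2041,58.2,20.8,2.6,2.0,55.8
Mozambique,Mozambique,2041,51.4,24.1,1.9,2.0,46.4
Djibouti,Djibouti,2047,53.5,28.6,0.05,2.5,46.9
Kyrgyzstan,Kyrgyzstan,2047,51.1,12.9,0.18,2.5,47.8
Burkina Faso,Burkina Faso,2047,51.4,21.6,1.42,2.5,46.2
Burundi,Burundi,2048,55.3,28.5,0.72,2.6,50.8
Cambodia,Cambodia,2048,59.9,15.6,0.71,2.6,57.8
Senegal,Senegal,2049,51.4,24.1,1.08,2.7,44.4
Sao Tome and Principe,Sao Tome and Principe,2051,57.1,15.8,0.01,2.9,55.7
Liberia,Liberia,2052,53.7,26.2,0.27,3.0,47.3
Timor-Leste,Timor-Leste,2053,55.8,29.1,0.08,3.1,50.6
Sierra Leone,Sierra Leone,2053,51.6,29.7,0.5,3.1,42.3
Bolivia (Plurinational State of),Bolivia (Plurinational State of),2053,63.5,17.6,0.45,3.1,62.8
Afghanistan,Afghanistan,2054,54.6,30.8,3.38,3.2,45.5
Niger,Niger,2054,48.1,29.1,2.12,3.2,37.0
Ghana,Ghana,2055,55.4,26.7,1.45,3.3,49.5
Guinea-Bissau,Guinea-Bissau,2056,48.2,30.1,0.09,3.4,36.9
Côte d'Ivoire,Cote d'Ivoire,2058,52.7,32.5,1.74,3.5,43.4
Congo,Congo,2060,55.3,29.8,0.33,3.7,50.7
Mali,Mali,2061,50.1,33.2,1.8,3.8,37.3
Comoros,Comoros,2063,56.4,36.1,0.07,4.0,47.4
Pakistan,Pakistan,2064,56.5,29.7,15.0,4.1,47.5
Cameroon,Cameroon,2065,53.5,33.0,1.71,4.2,44.3
Philippines,Philippines,2066,59.8,18.5,4.42,4.3,58.0
State of Palestine,State of Palestine,2067,59.3,13.0,0.24,4.4,56.7
Mauritania,Mauritania,2067,52.5,37.7,0.35,4.4,40.1
Nigeria,Nigeria,2068,49.9,36.8,15.88,4.5,33.3
Guinea,Guinea,2068,50.1,39.1,1.09,4.5,31.6
Eritrea,Eritrea,2069,53.5,41.2,0.27,4.5,38.3
Haiti,Haiti,2070,59.6,26.3,0.51,4.6,57.1
Togo,Togo,2070,55.0,33.9,0.58,4.6,45.6
Tajikistan,Tajikistan,2071,53.6,25.2,0.57,4.7,47.3
Benin,Benin,2074,52.8,39.6,1.08,5.0,40.1
Central African Republic,Central African Republic,2076,51.2,36.1,0.41,5.2,38.6
Iraq,Iraq,2076,59.3,20.4,2.46,5.2,54.7
Yemen,Yemen,2076,60.6,26.4,1.97,5.2,55.1
Sudan,Sudan,2077,52.5,38.6,3.42,5.3,37.1
Gambia,Gambia,2086,51.6,41.3,0.21,6.1,31.9
South Sudan,South Sudan,2089,54.4,49.4,1.1,6.4,30.7
Democratic Republic of the Congo,Democratic Republic of the Congo,2091,54.7,44.1,7.7,6.5,42.1
Somalia,Somalia,2092,54.3,50.8,1.37,6.6,29.9
Solomon Islands,Solomon Islands,2100,48.4,22.3,0.03,7.4,43.7
Papua New Guinea,Papua New Guinea,2100,50.4,21.8,0.45,7.4,46.1
Chad,Chad,2100,41.0,36.1,1.3,7.4,24.7
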