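name,management_type,area_km2,perimeter_km,established
Al Sareen,Especially Important Area,785.10,165.91,1976
Ras Al Shajer,Especially Important Area,102.07,47.93,1985
Khawr Salalah,Especially Important Area,0.67,3.93,1986
Al Wusta Wildlife Sanctuary,Wildlife Sanctuary,3013.24,239.44,1994
Dimaniyat Islands,Nature Reserve,233.64,77.84,1996
Turtle Reserve,Coastal Reserve,302.25,103.26,1996
Jabal Samhan,Nature Reserve,5057.49,287.35,1997
Khawr Mughsayl,Reserve,0.16,2.26,1997
Khawr Baleed,Reserve,0.77,5.52,1997
Khawr Sawli,Reserve,0.83,4.51,1997
Khawr Dahareez,Reserve,0.81,4.24,1997
Khawr Taqah,Reserve,0.97,4.58,1997
Khawr Rawri,Reserve,0.87,4.35,1997
Khawr Awqad,Reserve,0.27,3.50,1997
Khawr Qurum Al Sagher,Reserve,0.04,0.83,1997
Khawr Qurum Al Kabeer,Reserve,0.11,1.52,1997
Al Saleel,National Park,159.43,61.77,1997
Al Khawair,Especially Important Area,0.32,4.27,2006
Jebel Akhdar,Scenic Reserve,133.06,76.00,2011
Al Qurum Ramsar Site,Ramsar Site,1.91,8.34,2013
Al Wusta Wetland Reserve,Wetland Reserve,2809.10,253.13,2014
Jebel Qahwan,Nature Reserve,313.41,80.22,2014
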