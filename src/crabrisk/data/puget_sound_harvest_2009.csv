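# 2009 commercial shellfish harvest in Puget Sound (PacFIN landings apportioned
# to Puget Sound Partnership action areas; South Central Puget Sound excluded).
# Biomass in kg/yr, prices in USD/kg, revenue in USD/yr. Per-area revenues are
# as published (rounded to 0.01e6 USD); species totals are kept separately as
# canonical values because published per-area rows do not always sum to them.
species_group,action_area,area_km2,harvest_kg,price_usd_per_kg,revenue_usd
hardshell_clam,Hood Canal,126,880000,5.28,4650000
hardshell_clam,North Central Puget Sound,41,45000,3.97,180000
hardshell_clam,Whatcom/San Juan,54,191000,4.46,850000
hardshell_clam,South Puget Sound,108,2118000,5.58,11820000
hardshell_clam,Strait of Juan de Fuca,104,41000,3.18,130000
hardshell_clam,Whidbey,90,136000,5.22,710000
oyster,Hood Canal,126,567000,8.34,4730000
oyster,North Central Puget Sound,41,5000,2.20,10000
oyster,Whatcom/San Juan,54,36000,11.85,430000
oyster,South Puget Sound,108,694000,12.03,8350000
oyster,Strait of Juan de Fuca,104,14000,8.08,110000
oyster,Whidbey,90,36000,11.85,430000
mussel,Hood Canal,126,1000,4.31,4310
mussel,North Central Puget Sound,41,0,0.00,0
mussel,Whatcom/San Juan,54,2000,5.51,10000
mussel,South Puget Sound,108,445000,4.61,2050000
mussel,Strait of Juan de Fuca,104,1000,7.35,10000
mussel,Whidbey,90,386000,7.21,2780000
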