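country,region,destruction_proxies
El Salvador,Latin America & Caribbean,
Ghana,Sub-Saharan Africa,Tanzania
India,South Asia,
Nicaragua,Latin America & Caribbean,
Peru,Latin America & Caribbean,Nicaragua;El Salvador
Philippines,East Asia & Pacific,
Romania,Europe & Central Asia,
Tanzania,Sub-Saharan Africa,
U.S.,North America,
West Bank,Middle East & North Africa,Tanzania
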