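11
Kinshasa
2
Bas-Congo Bandundu
Bas-Congo
2
Kinshasa Bandundu
Bandundu
4
Kinshasa Bas-Congo Equateur Kasai-Occidental
Equateur
4
Bandundu Orientale Kasai-Occidental Kasai-Oriental
Orientale
4
Equateur North-Kivu Maniema Kasai-Oriental
North-Kivu
3
Orientale South-Kivu Maniema
South-Kivu
3
North-Kivu Maniema Katanga
Maniema
5
Orientale North-Kivu South-Kivu Katanga Kasai-Oriental
Katanga
3
South-Kivu Maniema Kasai-Oriental
Kasai-Oriental
5
Equateur Orientale Maniema Katanga Kasai-Occidental
Kasai-Occidental
3
Bandundu Equateur Kasai-Oriental
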