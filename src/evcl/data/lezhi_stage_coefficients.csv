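year,urbanization,coefficient
1980,0.077,0.0651
1985,0.0993,0.0839
1990,0.1006,0.085
1995,0.1228,0.1038
2000,0.1507,0.1274
2005,0.1911,0.1615
2010,0.289,0.2443
2015,0.324,0.2739
2020,0.405,0.3424
2025,0.4277,0.3616
2030,0.4469,0.3778
2035,0.4666,0.3944
2040,0.4868,0.4115
2045,0.5076,0.4291
2050,0.5289,0.4471
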