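year,surgeries,growth_rate
1998,666,
1999,1641,-0.11
2000,1468,0.45
2001,2273,-0.20
2002,1852,0.18
2003,2213,-0.39
2004,1480,-0.11
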