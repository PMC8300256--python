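year,surgeries,growth_rate
1992,81,
1993,1768,-0.08
1994,1630,-0.18
1995,1104,0.30
1996,1443,-0.02
1997,1323,0.06
1998,1418,-0.56
1999,1050,-0.01
2000,1041,0.03
2001,1062,0.12
2002,1188,0.25
2003,1514,-0.08
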