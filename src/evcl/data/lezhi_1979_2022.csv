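year,urbanization_rate,gdp_growth_rate
1979,7.59,9.971490633
1980,7.70,11.05487316
1981,8.14,10.2378835
1982,8.38,12.59957648
1983,8.52,11.33300497
1984,8.83,13.4210103
1985,9.93,14.87535903
1986,9.81,7.754043709
1987,9.82,11.84828693
1988,10.00,19.33459687
1989,10.05,15.91440774
1990,10.06,22.50407347
1991,10.19,2.691877513
1992,10.36,7.709403471
1993,10.92,19.57202006
1994,12.06,24.61830316
1995,12.28,28.64487959
1996,12.49,15.69714811
1997,12.87,11.19613098
1998,13.19,4.439076282
1999,14.03,2.448275862
2000,15.07,4.547549388
2001,15.98,6.765826139
2002,16.98,3.949767347
2003,18.00,14.34813073
2004,18.97,21.66059769
2005,19.11,13.00814834
2006,19.30,13.44171642
2007,20.90,21.17161303
2008,24.70,22.76540293
2009,27.50,10.09854288
2010,28.90,21.04877967
2011,29.20,19.45972077
2012,29.90,13.41095149
2013,30.80,9.436224616
2014,31.50,6.543723721
2015,32.40,7.721441915
2016,35.20,12.39096056
2017,36.40,6.757797573
2018,37.70,5.934806154
2019,39.20,9.176482397
2020,40.50,4.199437467
2021,41.32,11.40810491
2022,41.64,3.095441791
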