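date,n_instrumented,n_associating,pct_associating,n_foraging_at_sea
2011-10-01,3,3,100,46
2011-10-03,5,5,100,46
2011-10-04,7,7,100,43
2011-10-18,3,3,100,59
2012-08-20,5,3,60,24
2012-08-22,5,5,100,24
2012-08-23,3,2,66.7,24
2012-09-25,3,2,66.7,39
2012-09-26,2,0,0,39
2012-09-27,2,2,100,39
2012-10-30,4,3,75,39
2012-10-31,4,3,75,39
2012-11-20,3,3,100,35
2012-11-21,2,2,100,35
2012-11-22,2,0,0,35
2012-12-02,3,3,100,35
2012-12-03,2,0,0,35
2012-12-12,4,2,50,22
2012-12-13,4,3,75,22
2013-01-18,3,2,66.7,32
2013-01-19,3,3,100,32
2013-01-21,2,2,100,32
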