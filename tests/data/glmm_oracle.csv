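y,x,site,species
0,0.285,S4,SP4
0,0.24,S1,SP4
0,0.325,S4,SP5
1,0.33,S3,SP1
0,0.285,S4,SP4
1,0.275,S4,SP3
0,0.31,S3,SP5
0,0.245,S2,SP3
1,0.285,S4,SP4
0,0.27,S3,SP4
1,0.275,S4,SP3
1,0.385,S4,SP2
1,0.37,S3,SP2
0,0.295,S2,SP5
0,0.31,S3,SP5
0,0.345,S4,SP1
1,0.345,S4,SP1
1,0.31,S3,SP5
1,0.255,S2,SP4
1,0.315,S2,SP1
0,0.345,S4,SP1
0,0.31,S3,SP5
1,0.285,S4,SP4
1,0.385,S4,SP2
1,0.345,S4,SP1
0,0.295,S2,SP5
1,0.275,S4,SP3
1,0.385,S4,SP2
1,0.34,S1,SP2
1,0.315,S2,SP1
0,0.255,S2,SP4
0,0.27,S3,SP4
0,0.33,S3,SP1
1,0.3,S1,SP1
1,0.245,S2,SP3
0,0.37,S3,SP2
0,0.27,S3,SP4
1,0.23,S1,SP3
0,0.295,S2,SP5
0,0.26,S3,SP3
0,0.285,S4,SP4
0,0.31,S3,SP5
1,0.315,S2,SP1
1,0.325,S4,SP5
1,0.23,S1,SP3
1,0.275,S4,SP3
0,0.33,S3,SP1
1,0.295,S2,SP5
1,0.37,S3,SP2
1,0.315,S2,SP1
1,0.26,S3,SP3
0,0.275,S4,SP3
1,0.355,S2,SP2
1,0.245,S2,SP3
1,0.355,S2,SP2
1,0.385,S4,SP2
0,0.31,S3,SP5
0,0.34,S1,SP2
0,0.295,S2,SP5
1,0.245,S2,SP3
1,0.37,S3,SP2
1,0.3,S1,SP1
1,0.345,S4,SP1
1,0.315,S2,SP1
1,0.355,S2,SP2
0,0.33,S3,SP1
1,0.34,S1,SP2
0,0.245,S2,SP3
0,0.345,S4,SP1
0,0.285,S4,SP4
1,0.275,S4,SP3
1,0.385,S4,SP2
1,0.385,S4,SP2
0,0.245,S2,SP3
0,0.255,S2,SP4
0,0.255,S2,SP4
0,0.345,S4,SP1
0,0.24,S1,SP4
1,0.295,S2,SP5
1,0.28,S1,SP5
0,0.34,S1,SP2
0,0.275,S4,SP3
0,0.3,S1,SP1
1,0.34,S1,SP2
0,0.31,S3,SP5
0,0.285,S4,SP4
0,0.27,S3,SP4
1,0.3,S1,SP1
1,0.26,S3,SP3
0,0.23,S1,SP3
1,0.34,S1,SP2
1,0.345,S4,SP1
0,0.28,S1,SP5
1,0.245,S2,SP3
1,0.34,S1,SP2
0,0.245,S2,SP3
0,0.27,S3,SP4
1,0.23,S1,SP3
1,0.355,S2,SP2
1,0.285,S4,SP4
0,0.27,S3,SP4
0,0.28,S1,SP5
1,0.315,S2,SP1
0,0.285,S4,SP4
0,0.23,S1,SP3
1,0.3,S1,SP1
1,0.37,S3,SP2
0,0.345,S4,SP1
0,0.385,S4,SP2
0,0.23,S1,SP3
0,0.28,S1,SP5
0,0.255,S2,SP4
1,0.245,S2,SP3
0,0.33,S3,SP1
0,0.285,S4,SP4
1,0.315,S2,SP1
1,0.33,S3,SP1
0,0.295,S2,SP5
1,0.285,S4,SP4
1,0.26,S3,SP3
1,0.245,S2,SP3
0,0.23,S1,SP3
1,0.245,S2,SP3
0,0.255,S2,SP4
0,0.285,S4,SP4
0,0.26,S3,SP3
1,0.245,S2,SP3
0,0.28,S1,SP5
0,0.3,S1,SP1
1,0.33,S3,SP1
0,0.33,S3,SP1
1,0.31,S3,SP5
0,0.34,S1,SP2
1,0.33,S3,SP1
1,0.385,S4,SP2
1,0.355,S2,SP2
0,0.24,S1,SP4
1,0.385,S4,SP2
1,0.3,S1,SP1
0,0.28,S1,SP5
1,0.315,S2,SP1
0,0.31,S3,SP5
0,0.27,S3,SP4
0,0.27,S3,SP4
1,0.385,S4,SP2
1,0.295,S2,SP5
1,0.26,S3,SP3
0,0.33,S3,SP1
0,0.255,S2,SP4
0,0.245,S2,SP3
0,0.285,S4,SP4
0,0.26,S3,SP3
1,0.315,S2,SP1
0,0.31,S3,SP5
0,0.34,S1,SP2
1,0.28,S1,SP5
0,0.31,S3,SP5
1,0.23,S1,SP3
1,0.31,S3,SP5
0,0.26,S3,SP3
1,0.28,S1,SP5
1,0.37,S3,SP2
0,0.27,S3,SP4
0,0.27,S3,SP4
0,0.255,S2,SP4
1,0.385,S4,SP2
1,0.37,S3,SP2
0,0.24,S1,SP4
1,0.295,S2,SP5
1,0.33,S3,SP1
0,0.31,S3,SP5
1,0.255,S2,SP4
0,0.37,S3,SP2
0,0.255,S2,SP4
1,0.23,S1,SP3
1,0.285,S4,SP4
0,0.23,S1,SP3
1,0.315,S2,SP1
1,0.355,S2,SP2
0,0.295,S2,SP5
1,0.355,S2,SP2
0,0.26,S3,SP3
1,0.275,S4,SP3
0,0.385,S4,SP2
0,0.255,S2,SP4
1,0.315,S2,SP1
0,0.275,S4,SP3
1,0.345,S4,SP1
1,0.37,S3,SP2
0,0.325,S4,SP5
0,0.27,S3,SP4
1,0.325,S4,SP5
0,0.33,S3,SP1
1,0.315,S2,SP1
0,0.285,S4,SP4
1,0.385,S4,SP2
1,0.345,S4,SP1
0,0.255,S2,SP4
0,0.345,S4,SP1
0,0.27,S3,SP4
0,0.255,S2,SP4
1,0.355,S2,SP2
0,0.345,S4,SP1
0,0.31,S3,SP5
0,0.285,S4,SP4
0,0.28,S1,SP5
1,0.355,S2,SP2
1,0.3,S1,SP1
0,0.24,S1,SP4
0,0.27,S3,SP4
1,0.33,S3,SP1
0,0.27,S3,SP4
1,0.295,S2,SP5
1,0.315,S2,SP1
1,0.325,S4,SP5
1,0.355,S2,SP2
1,0.3,S1,SP1
1,0.26,S3,SP3
1,0.37,S3,SP2
1,0.37,S3,SP2
0,0.23,S1,SP3
1,0.325,S4,SP5
1,0.33,S3,SP1
1,0.345,S4,SP1
0,0.24,S1,SP4
1,0.275,S4,SP3
1,0.315,S2,SP1
1,0.37,S3,SP2
1,0.28,S1,SP5
1,0.33,S3,SP1
1,0.315,S2,SP1
1,0.355,S2,SP2
1,0.31,S3,SP5
0,0.255,S2,SP4
0,0.255,S2,SP4
1,0.28,S1,SP5
1,0.33,S3,SP1
1,0.385,S4,SP2
1,0.385,S4,SP2
0,0.33,S3,SP1
1,0.345,S4,SP1
1,0.37,S3,SP2
0,0.33,S3,SP1
1,0.315,S2,SP1
0,0.26,S3,SP3
1,0.26,S3,SP3
1,0.31,S3,SP5
1,0.315,S2,SP1
1,0.31,S3,SP5
0,0.315,S2,SP1
1,0.33,S3,SP1
1,0.385,S4,SP2
0,0.275,S4,SP3
1,0.31,S3,SP5
0,0.285,S4,SP4
1,0.315,S2,SP1
1,0.28,S1,SP5
1,0.345,S4,SP1
1,0.385,S4,SP2
1,0.34,S1,SP2
1,0.385,S4,SP2
0,0.27,S3,SP4
0,0.31,S3,SP5
0,0.285,S4,SP4
1,0.345,S4,SP1
1,0.345,S4,SP1
1,0.385,S4,SP2
1,0.37,S3,SP2
1,0.325,S4,SP5
0,0.27,S3,SP4
1,0.275,S4,SP3
1,0.255,S2,SP4
1,0.31,S3,SP5
1,0.315,S2,SP1
1,0.315,S2,SP1
0,0.285,S4,SP4
0,0.345,S4,SP1
0,0.345,S4,SP1
1,0.275,S4,SP3
0,0.315,S2,SP1
0,0.295,S2,SP5
1,0.31,S3,SP5
0,0.31,S3,SP5
1,0.28,S1,SP5
1,0.275,S4,SP3
0,0.28,S1,SP5
0,0.245,S2,SP3
1,0.385,S4,SP2
1,0.23,S1,SP3
1,0.295,S2,SP5
0,0.255,S2,SP4
1,0.255,S2,SP4
1,0.345,S4,SP1
0,0.31,S3,SP5
0,0.28,S1,SP5
1,0.345,S4,SP1
1,0.24,S1,SP4
1,0.3,S1,SP1
0,0.26,S3,SP3
0,0.24,S1,SP4
0,0.255,S2,SP4
0,0.275,S4,SP3
0,0.37,S3,SP2
0,0.315,S2,SP1
0,0.28,S1,SP5
1,0.37,S3,SP2
0,0.37,S3,SP2
1,0.34,S1,SP2
0,0.285,S4,SP4
0,0.23,S1,SP3
1,0.325,S4,SP5
1,0.37,S3,SP2
1,0.275,S4,SP3
0,0.245,S2,SP3
1,0.275,S4,SP3
1,0.23,S1,SP3
0,0.31,S3,SP5
1,0.325,S4,SP5
1,0.345,S4,SP1
0,0.26,S3,SP3
0,0.26,S3,SP3
0,0.26,S3,SP3
1,0.295,S2,SP5
0,0.285,S4,SP4
0,0.24,S1,SP4
0,0.28,S1,SP5
0,0.24,S1,SP4
1,0.26,S3,SP3
0,0.3,S1,SP1
1,0.295,S2,SP5
0,0.255,S2,SP4
0,0.325,S4,SP5
0,0.245,S2,SP3
1,0.355,S2,SP2
0,0.285,S4,SP4
0,0.23,S1,SP3
1,0.355,S2,SP2
1,0.33,S3,SP1
1,0.34,S1,SP2
0,0.315,S2,SP1
1,0.295,S2,SP5
1,0.345,S4,SP1
0,0.24,S1,SP4
1,0.28,S1,SP5
1,0.315,S2,SP1
1,0.31,S3,SP5
1,0.355,S2,SP2
1,0.315,S2,SP1
0,0.26,S3,SP3
0,0.24,S1,SP4
0,0.285,S4,SP4
0,0.27,S3,SP4
0,0.245,S2,SP3
1,0.295,S2,SP5
1,0.37,S3,SP2
0,0.295,S2,SP5
0,0.285,S4,SP4
1,0.385,S4,SP2
1,0.315,S2,SP1
0,0.34,S1,SP2
0,0.345,S4,SP1
0,0.295,S2,SP5
0,0.275,S4,SP3
1,0.355,S2,SP2
0,0.385,S4,SP2
0,0.285,S4,SP4
1,0.345,S4,SP1
1,0.355,S2,SP2
0,0.23,S1,SP3
0,0.31,S3,SP5
0,0.315,S2,SP1
0,0.23,S1,SP3
1,0.315,S2,SP1
1,0.345,S4,SP1
0,0.33,S3,SP1
1,0.325,S4,SP5
1,0.34,S1,SP2
1,0.34,S1,SP2
0,0.24,S1,SP4
0,0.23,S1,SP3
0,0.27,S3,SP4
0,0.325,S4,SP5
1,0.28,S1,SP5
0,0.23,S1,SP3
0,0.34,S1,SP2
1,0.345,S4,SP1
0,0.245,S2,SP3
0,0.295,S2,SP5
1,0.31,S3,SP5
0,0.245,S2,SP3
1,0.255,S2,SP4
1,0.345,S4,SP1
0,0.315,S2,SP1
0,0.355,S2,SP2
1,0.37,S3,SP2
1,0.31,S3,SP5
0,0.245,S2,SP3
1,0.245,S2,SP3
0,0.255,S2,SP4
1,0.345,S4,SP1
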