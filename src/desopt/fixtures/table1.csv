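run,liquid_solid_ratio,ultrasonic_power,extraction_time,response
1,20,600,50,13.36
2,30,600,40,14.94
3,30,600,40,14.86
4,30,600,40,14.75
5,20,600,30,12.93
6,30,750,30,14.42
7,40,600,30,14.61
8,20,450,40,13.71
9,40,750,40,14.26
10,30,450,50,14.07
11,30,450,30,12.86
12,40,450,40,14.72
13,30,600,40,14.95
14,40,600,50,14.79
15,20,750,40,13.50
16,30,750,50,13.66
17,30,600,40,14.90
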