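patient_id,group,time_to_event_months,dose_gy,fractions,n_pri,n_ovl
1,recurrent,5,70,35,13758,4410
2,recurrent,7,70,35,10954,1679
3,recurrent,9,70,35,2235,906
4,recurrent,9,70,35,1867,868
5,recurrent,11,70,35,11981,4116
6,recurrent,16,70,35,12388,2187
7,recurrent,23,66,33,18197,153
8,recurrent,30,70,35,18681,462
9,recurrent,46,70,35,3537,1832
10,non_recurrent,37,70,35,11976,0
11,non_recurrent,40,70,35,5610,0
12,non_recurrent,41,70,35,18610,0
13,non_recurrent,43,70,35,8478,0
14,non_recurrent,44,70,35,30802,0
15,non_recurrent,45,70,35,4116,0
16,non_recurrent,48,70,35,3756,0
17,non_recurrent,50,70,35,39955,0
18,non_recurrent,53,70,35,1220,0
19,non_recurrent,54,70,35,16309,0
20,non_recurrent,60,70,35,5498,0
21,non_recurrent,61,70,35,2660,0
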