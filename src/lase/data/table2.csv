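patient_id,substrate,af_type,basal_rhythm,entropy_original,lase,recurrence
1,normal,paroxysmal,SR,6.206,6.693,no
2,normal,paroxysmal,SR,6.135,6.543,no
3,normal,paroxysmal,SR,5.804,6.533,no
4,abnormal,persistent,AF,4.374,4.885,yes
5,normal,paroxysmal,AF,5.892,6.358,no
6,abnormal,persistent,AF,4.170,4.532,no
7,normal,paroxysmal,AF,6.319,6.767,no
8,normal,paroxysmal,AF,6.737,6.998,no
9,abnormal,persistent,AF,5.557,5.831,no
10,normal,paroxysmal,SR,5.803,5.940,no
11,normal,persistent,AF,5.509,5.755,no
12,abnormal,persistent,SR,5.652,5.988,no
13,abnormal,persistent,AF,5.448,4.839,yes
14,normal,paroxysmal,AF,6.535,6.767,no
15,normal,paroxysmal,SR,6.556,6.960,no
16,abnormal,persistent,AF,5.281,5.707,no
17,normal,paroxysmal,SR,5.872,6.251,no
18,normal,paroxysmal,SR,5.914,6.380,no
19,normal,persistent,AF,5.101,5.439,no
20,normal,paroxysmal,SR,6.662,7.167,no
21,normal,paroxysmal,SR,6.216,6.665,no
22,abnormal,persistent,AF,5.156,5.432,no
23,normal,paroxysmal,SR,6.625,7.096,no
24,normal,paroxysmal,SR,6.340,6.594,no
25,abnormal,persistent,AF,5.354,5.573,no
26,abnormal,paroxysmal,SR,5.228,5.872,no
27,abnormal,persistent,AF,5.310,5.500,no
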