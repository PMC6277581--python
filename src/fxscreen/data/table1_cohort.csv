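sample_id,sex,alleles,status
001,M,29,NL
002,M,31,NL
003,M,30,NL
004,M,37,NL
005,M,35,NL
006,M,39,NL
007,M,30,NL
008,F,30;30,NL
009,F,30;30,NL
010,F,30;30,NL
011,F,30;30,NL
012,M,22,NL
013,M,31,NL
014,M,31,NL
015,M,31,NL
016,M,29,NL
017,F,28;30,NL
018,F,31;31,NL
019,M,31,NL
021,F,31;31,NL
022,M,35,NL
023,F,30;39,NL
024,F,29;32,NL
025,F,31;31,NL
026,M,31,NL
027,M,31,NL
028,F,29;29,NL
029,M,36,NL
030,M,29,NL
031,M,30,NL
032,M,38,NL
033,F,30;30,NL
034,M,30,NL
035,M,30,NL
037,M,32,NL
038,M,30,NL
039,F,29;29,NL
040,F,30;30,NL
041,F,30;30,NL
042,M,37,NL
043,F,31;32,NL
044,M,545,FM
045,F,28;30,NL
046,M,31,NL
049,F,29;29,NL
051,M,31,NL
052,F,40;40,NL
053,F,30;30,NL
054,M,29;51,NL
055,F,29;30,NL
056,M,31,NL
057,F,30;36,NL
058,M,30,NL
059,F,28;28,NL
060,M,29,NL
061,F,20;20,NL
062,F,27;35,NL
063,F,29;29,NL
064,F,29;36,NL
065,M,30,NL
066,M,28,NL
067,F,29;36,NL
068,F,24;26,NL
069,M,26,NL
070,M,33,NL
071,F,26;26,NL
072,M,37,NL
073,M,27,NL
074,M,26,NL
075,F,27;34,NL
076,M,28,NL
077,M,28,NL
078,M,28,NL
079,M,29,NL
080,F,28;28,NL
081,F,30;30,NL
082,M,29,NL
083,M,30,NL
084,F,30;30,NL
085,M,29,NL
086,F,29;29,NL
087,M,36,NL
088,F,28;28,NL
089,F,28;28,NL
090,M,29,NL
091,M,30,NL
092,F,28;28,NL
093,F,27;27,NL
094,F,30;30,NL
095,M,20,NL
096,M,29,NL
097,M,21,NL
098,F,28;35,NL
099,F,28;35,NL
100,F,28;40,NL
101,F,27;27,NL
102,M,27,NL
103,M,26,NL
104,F,27;27,NL
105,F,25;25,NL
106,M,28,NL
107,M,30,NL
113,F,29;29,NL
114,M,110,PM
125,M,29,NL
126,M,30,NL
127,M,23,NL
128,M,30,NL
131,M,29,NL
133,M,32,NL
136,F,20;28,NL
137,F,15;29,NL
138,M,31,NL
139,F,20;30,NL
140,F,28;28,NL
141,F,28;28,NL
142,F,25;30,NL
143,F,29;31,NL
144,F,30;30,NL
145,M,30,NL
146,M,10,NL
147,F,28;28,NL
148,M,30,NL
149,M,83,PM
150,F,29;29,NL
151,F,22;30,NL
152,F,29;128,PM
153,M,29,NL
154,F,28;110;222;441;504;900,FM
155,F,29;29,NL
156,F,31;31,NL
157,F,25;185;324;551;658;800,FM
158,M,30,NL
159,F,32;423-850,FM
160,F,24;225,FM
161,F,31;31,NL
162,F,29;76,PM
163,M,36,NL
164,M,29,NL
165,F,28;288;532,FM
166,F,28;223;446;769,FM
167,M,29,NL
168,M,29,NL
169,F,29;125,PM
170,F,30;30,NL
171,F,34;290,FM
172,F,30;101,PM
210,F,28;28,NL
211,M,29,NL
212,F,30;150,PM
213,F,29;29,NL
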