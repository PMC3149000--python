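mu,protein,RNA,DNA,lipid,LPS,murein,glycogen,other,d_BmAla,d_BmVli,d_BmSer,d_BmAsp,d_BmGlu,d_BmAro,d_BmHis,d_BmRnaPur,d_BmRnaPyr,d_BmDnaPur,d_BmDnaPyr,d_BmAcyl,d_BmGlyc3P,d_BmLps,d_BmMurein,d_BmGlycogen,d_BmC1,d_BmAssembly
0.1,0.61,0.14,0.031,0.093,0.034,0.025,0.025,0.042,0.5545454545454546,1.1645454545454543,0.8318181818181817,1.1645454545454543,1.22,0.4436363636363636,0.16636363636363635,0.2246913580246914,0.2074074074074074,0.05016181229773463,0.05016181229773463,0.248,0.124,0.17,0.1,0.15432098765432098,0.35000000000000003,65.0
0.2,0.585,0.165,0.031,0.093,0.034,0.025,0.025,0.042,0.5318181818181817,1.1168181818181817,0.7977272727272726,1.1168181818181817,1.17,0.4254545454545454,0.15954545454545452,0.26481481481481484,0.24444444444444446,0.05016181229773463,0.05016181229773463,0.248,0.124,0.17,0.1,0.15432098765432098,0.35000000000000003,65.0
0.3,0.56,0.185,0.031,0.093,0.034,0.025,0.025,0.047,0.5090909090909091,1.0690909090909093,0.7636363636363638,1.0690909090909093,1.12,0.40727272727272734,0.15272727272727274,0.29691358024691356,0.2740740740740741,0.05016181229773463,0.05016181229773463,0.248,0.124,0.17,0.1,0.15432098765432098,0.39166666666666666,65.0
0.4,0.535,0.205,0.031,0.093,0.034,0.025,0.025,0.052,0.48636363636363644,1.0213636363636365,0.7295454545454546,1.0213636363636365,1.07,0.38909090909090915,0.14590909090909093,0.32901234567901233,0.30370370370370364,0.05016181229773463,0.05016181229773463,0.248,0.124,0.17,0.1,0.15432098765432098,0.43333333333333335,65.0
0.48,0.52,0.208,0.031,0.093,0.034,0.025,0.025,0.064,0.4727272727272728,0.9927272727272728,0.7090909090909091,0.9927272727272728,1.04,0.37818181818181823,0.14181818181818182,0.33382716049382716,0.3081481481481481,0.05016181229773463,0.05016181229773463,0.248,0.124,0.17,0.1,0.15432098765432098,0.5333333333333333,65.0
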