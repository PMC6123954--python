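# synthetic stand-in panel: sizes match the study's curated list; symbols beyond the seeded real ones are synthetic
GJB2
MYO6
HOMER2
WFS1
GPR98
PAX2
TECTA
LRIG3
LAMA2
CDH23
DMD
DUOX2
RBPJ
USH2A
COL11A1
NAV2
CPXM2
COL4A4
LRP2
MYO15A
MYH9
TSPEAR
PCDH15
OTOG
MECOM
NTN1
TCOF1
COL11A2
CELSR1
SLC9A3R1
COL9A1
TJP2
ALMS1
JAG1
ATP2B2
SLC26A4
LRIG1
LOXHD1
CHRNA9
RDX
CHD7
NTF3
ELMOD3
SLC4A7
ATP8B1
NPC1
KARS
ERCC6
WBP2
MIR96
KCNQ1
OTOF
SYNDFN0001
SYNDFN0002
SYNDFN0003
SYNDFN0004
SYNDFN0005
SYNDFN0006
SYNDFN0007
SYNDFN0008
SYNDFN0009
SYNDFN0010
SYNDFN0011
SYNDFN0012
SYNDFN0013
SYNDFN0014
SYNDFN0015
SYNDFN0016
SYNDFN0017
SYNDFN0018
SYNDFN0019
SYNDFN0020
SYNDFN0021
SYNDFN0022
SYNDFN0023
SYNDFN0024
SYNDFN0025
SYNDFN0026
SYNDFN0027
SYNDFN0028
SYNDFN0029
SYNDFN0030
SYNDFN0031
SYNDFN0032
SYNDFN0033
SYNDFN0034
SYNDFN0035
SYNDFN0036
SYNDFN0037
SYNDFN0038
SYNDFN0039
SYNDFN0040
SYNDFN0041
SYNDFN0042
SYNDFN0043
SYNDFN0044
SYNDFN0045
SYNDFN0046
SYNDFN0047
SYNDFN0048
SYNDFN0049
SYNDFN0050
SYNDFN0051
SYNDFN0052
SYNDFN0053
SYNDFN0054
SYNDFN0055
SYNDFN0056
SYNDFN0057
SYNDFN0058
SYNDFN0059
SYNDFN0060
SYNDFN0061
SYNDFN0062
SYNDFN0063
SYNDFN0064
SYNDFN0065
SYNDFN0066
SYNDFN0067
SYNDFN0068
SYNDFN0069
SYNDFN0070
SYNDFN0071
SYNDFN0072
SYNDFN0073
SYNDFN0074
SYNDFN0075
SYNDFN0076
SYNDFN0077
SYNDFN0078
SYNDFN0079
SYNDFN0080
SYNDFN0081
SYNDFN0082
SYNDFN0083
SYNDFN0084
SYNDFN0085
SYNDFN0086
SYNDFN0087
SYNDFN0088
SYNDFN0089
SYNDFN0090
SYNDFN0091
SYNDFN0092
SYNDFN0093
SYNDFN0094
SYNDFN0095
SYNDFN0096
SYNDFN0097
SYNDFN0098
SYNDFN0099
SYNDFN0100
SYNDFN0101
SYNDFN0102
SYNDFN0103
SYNDFN0104
SYNDFN0105
SYNDFN0106
SYNDFN0107
SYNDFN0108
SYNDFN0109
SYNDFN0110
SYNDFN0111
SYNDFN0112
SYNDFN0113
SYNDFN0114
SYNDFN0115
SYNDFN0116
SYNDFN0117
SYNDFN0118
SYNDFN0119
SYNDFN0120
SYNDFN0121
SYNDFN0122
SYNDFN0123
SYNDFN0124
SYNDFN0125
SYNDFN0126
SYNDFN0127
SYNDFN0128
SYNDFN0129
SYNDFN0130
SYNDFN0131
SYNDFN0132
SYNDFN0133
SYNDFN0134
SYNDFN0135
SYNDFN0136
SYNDFN0137
SYNDFN0138
SYNDFN0139
SYNDFN0140
SYNDFN0141
SYNDFN0142
SYNDFN0143
SYNDFN0144
SYNDFN0145
SYNDFN0146
SYNDFN0147
SYNDFN0148
SYNDFN0149
SYNDFN0150
SYNDFN0151
SYNDFN0152
SYNDFN0153
SYNDFN0154
SYNDFN0155
SYNDFN0156
SYNDFN0157
SYNDFN0158
SYNDFN0159
SYNDFN0160
SYNDFN0161
SYNDFN0162
SYNDFN0163
SYNDFN0164
SYNDFN0165
SYNDFN0166
SYNDFN0167
SYNDFN0168
SYNDFN0169
SYNDFN0170
SYNDFN0171
SYNDFN0172
SYNDFN0173
SYNDFN0174
SYNDFN0175
SYNDFN0176
SYNDFN0177
SYNDFN0178
SYNDFN0179
SYNDFN0180
SYNDFN0181
SYNDFN0182
SYNDFN0183
SYNDFN0184
SYNDFN0185
SYNDFN0186
SYNDFN0187
SYNDFN0188
SYNDFN0189
SYNDFN0190
SYNDFN0191
SYNDFN0192
SYNDFN0193
SYNDFN0194
SYNDFN0195
SYNDFN0196
SYNDFN0197
SYNDFN0198
SYNDFN0199
SYNDFN0200
SYNDFN0201
SYNDFN0202
SYNDFN0203
SYNDFN0204
SYNDFN0205
SYNDFN0206
SYNDFN0207
SYNDFN0208
SYNDFN0209
SYNDFN0210
SYNDFN0211
SYNDFN0212
SYNDFN0213
SYNDFN0214
SYNDFN0215
SYNDFN0216
SYNDFN0217
SYNDFN0218
SYNDFN0219
SYNDFN0220
SYNDFN0221
SYNDFN0222
SYNDFN0223
SYNDFN0224
SYNDFN0225
SYNDFN0226
SYNDFN0227
SYNDFN0228
SYNDFN0229
SYNDFN0230
SYNDFN0231
SYNDFN0232
SYNDFN0233
SYNDFN0234
SYNDFN0235
SYNDFN0236
SYNDFN0237
SYNDFN0238
SYNDFN0239
SYNDFN0240
SYNDFN0241
SYNDFN0242
SYNDFN0243
SYNDFN0244
SYNDFN0245
SYNDFN0246
SYNDFN0247
SYNDFN0248
SYNDFN0249
SYNDFN0250
SYNDFN0251
SYNDFN0252
SYNDFN0253
SYNDFN0254
SYNDFN0255
SYNDFN0256
SYNDFN0257
SYNDFN0258
SYNDFN0259
SYNDFN0260
SYNDFN0261
SYNDFN0262
SYNDFN0263
SYNDFN0264
SYNDFN0265
SYNDFN0266
SYNDFN0267
SYNDFN0268
SYNDFN0269
SYNDFN0270
SYNDFN0271
SYNDFN0272
SYNDFN0273
SYNDFN0274
SYNDFN0275
SYNDFN0276
SYNDFN0277
SYNDFN0278
SYNDFN0279
SYNDFN0280
SYNDFN0281
SYNDFN0282
SYNDFN0283
SYNDFN0284
SYNDFN0285
SYNDFN0286
SYNDFN0287
SYNDFN0288
SYNDFN0289
SYNDFN0290
SYNDFN0291
SYNDFN0292
SYNDFN0293
SYNDFN0294
SYNDFN0295
SYNDFN0296
SYNDFN0297
SYNDFN0298
SYNDFN0299
SYNDFN0300
SYNDFN0301
SYNDFN0302
SYNDFN0303
SYNDFN0304
SYNDFN0305
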