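# synthetic stand-in panel: sizes match the study's curated list; symbols beyond the seeded real ones are synthetic
RHO
RPGR
ABCA4
USH2A
RPE65
CRB1
PRPH2
SYNRET0001
SYNRET0002
SYNRET0003
SYNRET0004
SYNRET0005
SYNRET0006
SYNRET0007
SYNRET0008
SYNRET0009
SYNRET0010
SYNRET0011
SYNRET0012
SYNRET0013
SYNRET0014
SYNRET0015
SYNRET0016
SYNRET0017
SYNRET0018
SYNRET0019
SYNRET0020
SYNRET0021
SYNRET0022
SYNRET0023
SYNRET0024
SYNRET0025
SYNRET0026
SYNRET0027
SYNRET0028
SYNRET0029
SYNRET0030
SYNRET0031
SYNRET0032
SYNRET0033
SYNRET0034
SYNRET0035
SYNRET0036
SYNRET0037
SYNRET0038
SYNRET0039
SYNRET0040
SYNRET0041
SYNRET0042
SYNRET0043
SYNRET0044
SYNRET0045
SYNRET0046
SYNRET0047
SYNRET0048
SYNRET0049
SYNRET0050
SYNRET0051
SYNRET0052
SYNRET0053
SYNRET0054
SYNRET0055
SYNRET0056
SYNRET0057
SYNRET0058
SYNRET0059
SYNRET0060
SYNRET0061
SYNRET0062
SYNRET0063
SYNRET0064
SYNRET0065
SYNRET0066
SYNRET0067
SYNRET0068
SYNRET0069
SYNRET0070
SYNRET0071
SYNRET0072
SYNRET0073
SYNRET0074
SYNRET0075
SYNRET0076
SYNRET0077
SYNRET0078
SYNRET0079
SYNRET0080
SYNRET0081
SYNRET0082
SYNRET0083
SYNRET0084
SYNRET0085
SYNRET0086
SYNRET0087
SYNRET0088
SYNRET0089
SYNRET0090
SYNRET0091
SYNRET0092
SYNRET0093
SYNRET0094
SYNRET0095
SYNRET0096
SYNRET0097
SYNRET0098
SYNRET0099
SYNRET0100
SYNRET0101
SYNRET0102
SYNRET0103
SYNRET0104
SYNRET0105
SYNRET0106
SYNRET0107
SYNRET0108
SYNRET0109
SYNRET0110
SYNRET0111
SYNRET0112
SYNRET0113
SYNRET0114
SYNRET0115
SYNRET0116
SYNRET0117
SYNRET0118
SYNRET0119
SYNRET0120
SYNRET0121
SYNRET0122
SYNRET0123
SYNRET0124
SYNRET0125
SYNRET0126
SYNRET0127
SYNRET0128
SYNRET0129
SYNRET0130
SYNRET0131
SYNRET0132
SYNRET0133
SYNRET0134
SYNRET0135
SYNRET0136
SYNRET0137
SYNRET0138
SYNRET0139
SYNRET0140
SYNRET0141
SYNRET0142
SYNRET0143
SYNRET0144
SYNRET0145
SYNRET0146
SYNRET0147
SYNRET0148
SYNRET0149
SYNRET0150
SYNRET0151
SYNRET0152
SYNRET0153
SYNRET0154
SYNRET0155
SYNRET0156
SYNRET0157
SYNRET0158
SYNRET0159
SYNRET0160
SYNRET0161
SYNRET0162
SYNRET0163
SYNRET0164
SYNRET0165
SYNRET0166
SYNRET0167
SYNRET0168
SYNRET0169
SYNRET0170
SYNRET0171
SYNRET0172
SYNRET0173
SYNRET0174
SYNRET0175
SYNRET0176
SYNRET0177
SYNRET0178
SYNRET0179
SYNRET0180
SYNRET0181
SYNRET0182
SYNRET0183
SYNRET0184
SYNRET0185
SYNRET0186
SYNRET0187
SYNRET0188
SYNRET0189
SYNRET0190
SYNRET0191
SYNRET0192
SYNRET0193
SYNRET0194
SYNRET0195
SYNRET0196
SYNRET0197
SYNRET0198
SYNRET0199
SYNRET0200
SYNRET0201
SYNRET0202
SYNRET0203
SYNRET0204
SYNRET0205
SYNRET0206
SYNRET0207
SYNRET0208
SYNRET0209
SYNRET0210
SYNRET0211
SYNRET0212
SYNRET0213
SYNRET0214
SYNRET0215
SYNRET0216
SYNRET0217
SYNRET0218
SYNRET0219
SYNRET0220
SYNRET0221
SYNRET0222
SYNRET0223
SYNRET0224
SYNRET0225
SYNRET0226
SYNRET0227
SYNRET0228
SYNRET0229
SYNRET0230
SYNRET0231
SYNRET0232
SYNRET0233
SYNRET0234
SYNRET0235
SYNRET0236
SYNRET0237
SYNRET0238
SYNRET0239
SYNRET0240
SYNRET0241
SYNRET0242
SYNRET0243
SYNRET0244
SYNRET0245
SYNRET0246
SYNRET0247
SYNRET0248
SYNRET0249
SYNRET0250
SYNRET0251
SYNRET0252
SYNRET0253
SYNRET0254
SYNRET0255
SYNRET0256
SYNRET0257
SYNRET0258
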