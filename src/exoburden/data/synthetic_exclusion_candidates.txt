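# synthetic stand-in panel: sizes match the study's curated list; symbols beyond the seeded real ones are synthetic
TTN
SIRPA
MUC4
MUC16
OBSCN
HYDIN
PDE4DIP
AHNAK2
SYNDFN0001
SYNDFN0002
SYNEXC0001
SYNEXC0002
SYNEXC0003
SYNEXC0004
SYNEXC0005
SYNEXC0006
SYNEXC0007
SYNEXC0008
SYNEXC0009
SYNEXC0010
SYNEXC0011
SYNEXC0012
SYNEXC0013
SYNEXC0014
SYNEXC0015
SYNEXC0016
SYNEXC0017
SYNEXC0018
SYNEXC0019
SYNEXC0020
SYNEXC0021
SYNEXC0022
SYNEXC0023
SYNEXC0024
SYNEXC0025
SYNEXC0026
SYNEXC0027
SYNEXC0028
SYNEXC0029
SYNEXC0030
SYNEXC0031
SYNEXC0032
SYNEXC0033
SYNEXC0034
SYNEXC0035
SYNEXC0036
SYNEXC0037
SYNEXC0038
SYNEXC0039
SYNEXC0040
SYNEXC0041
SYNEXC0042
SYNEXC0043
SYNEXC0044
SYNEXC0045
SYNEXC0046
SYNEXC0047
SYNEXC0048
SYNEXC0049
SYNEXC0050
SYNEXC0051
SYNEXC0052
SYNEXC0053
SYNEXC0054
SYNEXC0055
SYNEXC0056
SYNEXC0057
SYNEXC0058
SYNEXC0059
SYNEXC0060
SYNEXC0061
SYNEXC0062
SYNEXC0063
SYNEXC0064
SYNEXC0065
SYNEXC0066
SYNEXC0067
SYNEXC0068
SYNEXC0069
SYNEXC0070
SYNEXC0071
SYNEXC0072
SYNEXC0073
SYNEXC0074
SYNEXC0075
SYNEXC0076
SYNEXC0077
SYNEXC0078
SYNEXC0079
SYNEXC0080
SYNEXC0081
SYNEXC0082
SYNEXC0083
SYNEXC0084
SYNEXC0085
SYNEXC0086
SYNEXC0087
SYNEXC0088
SYNEXC0089
SYNEXC0090
SYNEXC0091
SYNEXC0092
SYNEXC0093
SYNEXC0094
SYNEXC0095
SYNEXC0096
SYNEXC0097
SYNEXC0098
SYNEXC0099
SYNEXC0100
SYNEXC0101
SYNEXC0102
SYNEXC0103
SYNEXC0104
SYNEXC0105
SYNEXC0106
SYNEXC0107
SYNEXC0108
SYNEXC0109
SYNEXC0110
SYNEXC0111
SYNEXC0112
SYNEXC0113
SYNEXC0114
SYNEXC0115
SYNEXC0116
SYNEXC0117
SYNEXC0118
SYNEXC0119
SYNEXC0120
SYNEXC0121
SYNEXC0122
SYNEXC0123
SYNEXC0124
SYNEXC0125
SYNEXC0126
SYNEXC0127
SYNEXC0128
SYNEXC0129
SYNEXC0130
SYNEXC0131
SYNEXC0132
SYNEXC0133
SYNEXC0134
SYNEXC0135
SYNEXC0136
SYNEXC0137
SYNEXC0138
SYNEXC0139
SYNEXC0140
SYNEXC0141
SYNEXC0142
SYNEXC0143
SYNEXC0144
SYNEXC0145
SYNEXC0146
SYNEXC0147
SYNEXC0148
SYNEXC0149
SYNEXC0150
SYNEXC0151
SYNEXC0152
SYNEXC0153
SYNEXC0154
SYNEXC0155
SYNEXC0156
SYNEXC0157
SYNEXC0158
SYNEXC0159
SYNEXC0160
SYNEXC0161
SYNEXC0162
SYNEXC0163
SYNEXC0164
SYNEXC0165
SYNEXC0166
SYNEXC0167
SYNEXC0168
SYNEXC0169
SYNEXC0170
SYNEXC0171
SYNEXC0172
SYNEXC0173
SYNEXC0174
SYNEXC0175
SYNEXC0176
SYNEXC0177
SYNEXC0178
SYNEXC0179
SYNEXC0180
SYNEXC0181
SYNEXC0182
SYNEXC0183
SYNEXC0184
SYNEXC0185
SYNEXC0186
SYNEXC0187
SYNEXC0188
SYNEXC0189
SYNEXC0190
SYNEXC0191
SYNEXC0192
SYNEXC0193
SYNEXC0194
SYNEXC0195
SYNEXC0196
SYNEXC0197
SYNEXC0198
SYNEXC0199
SYNEXC0200
SYNEXC0201
SYNEXC0202
SYNEXC0203
SYNEXC0204
SYNEXC0205
SYNEXC0206
SYNEXC0207
SYNEXC0208
SYNEXC0209
SYNEXC0210
SYNEXC0211
SYNEXC0212
SYNEXC0213
SYNEXC0214
SYNEXC0215
SYNEXC0216
SYNEXC0217
SYNEXC0218
SYNEXC0219
SYNEXC0220
SYNEXC0221
SYNEXC0222
SYNEXC0223
SYNEXC0224
SYNEXC0225
SYNEXC0226
SYNEXC0227
SYNEXC0228
SYNEXC0229
SYNEXC0230
SYNEXC0231
SYNEXC0232
SYNEXC0233
SYNEXC0234
SYNEXC0235
SYNEXC0236
SYNEXC0237
SYNEXC0238
SYNEXC0239
SYNEXC0240
SYNEXC0241
SYNEXC0242
SYNEXC0243
SYNEXC0244
SYNEXC0245
SYNEXC0246
SYNEXC0247
SYNEXC0248
SYNEXC0249
SYNEXC0250
SYNEXC0251
SYNEXC0252
SYNEXC0253
SYNEXC0254
SYNEXC0255
SYNEXC0256
SYNEXC0257
SYNEXC0258
SYNEXC0259
SYNEXC0260
SYNEXC0261
SYNEXC0262
SYNEXC0263
SYNEXC0264
SYNEXC0265
SYNEXC0266
SYNEXC0267
SYNEXC0268
SYNEXC0269
SYNEXC0270
SYNEXC0271
SYNEXC0272
SYNEXC0273
SYNEXC0274
SYNEXC0275
SYNEXC0276
SYNEXC0277
SYNEXC0278
SYNEXC0279
SYNEXC0280
SYNEXC0281
SYNEXC0282
SYNEXC0283
SYNEXC0284
SYNEXC0285
SYNEXC0286
SYNEXC0287
SYNEXC0288
SYNEXC0289
SYNEXC0290
SYNEXC0291
SYNEXC0292
SYNEXC0293
SYNEXC0294
SYNEXC0295
SYNEXC0296
SYNEXC0297
SYNEXC0298
SYNEXC0299
SYNEXC0300
SYNEXC0301
SYNEXC0302
SYNEXC0303
SYNEXC0304
SYNEXC0305
SYNEXC0306
SYNEXC0307
SYNEXC0308
SYNEXC0309
SYNEXC0310
SYNEXC0311
SYNEXC0312
SYNEXC0313
SYNEXC0314
SYNEXC0315
SYNEXC0316
SYNEXC0317
SYNEXC0318
SYNEXC0319
SYNEXC0320
SYNEXC0321
SYNEXC0322
SYNEXC0323
SYNEXC0324
SYNEXC0325
SYNEXC0326
SYNEXC0327
SYNEXC0328
SYNEXC0329
SYNEXC0330
SYNEXC0331
SYNEXC0332
SYNEXC0333
SYNEXC0334
SYNEXC0335
SYNEXC0336
SYNEXC0337
SYNEXC0338
SYNEXC0339
SYNEXC0340
SYNEXC0341
SYNEXC0342
SYNEXC0343
SYNEXC0344
SYNEXC0345
SYNEXC0346
SYNEXC0347
SYNEXC0348
SYNEXC0349
SYNEXC0350
SYNEXC0351
SYNEXC0352
SYNEXC0353
SYNEXC0354
SYNEXC0355
SYNEXC0356
SYNEXC0357
SYNEXC0358
SYNEXC0359
SYNEXC0360
SYNEXC0361
SYNEXC0362
SYNEXC0363
SYNEXC0364
SYNEXC0365
SYNEXC0366
SYNEXC0367
SYNEXC0368
SYNEXC0369
SYNEXC0370
SYNEXC0371
SYNEXC0372
SYNEXC0373
SYNEXC0374
SYNEXC0375
SYNEXC0376
SYNEXC0377
SYNEXC0378
SYNEXC0379
SYNEXC0380
SYNEXC0381
SYNEXC0382
SYNEXC0383
SYNEXC0384
SYNEXC0385
SYNEXC0386
SYNEXC0387
SYNEXC0388
SYNEXC0389
SYNEXC0390
SYNEXC0391
SYNEXC0392
SYNEXC0393
SYNEXC0394
SYNEXC0395
SYNEXC0396
SYNEXC0397
SYNEXC0398
SYNEXC0399
SYNEXC0400
SYNEXC0401
SYNEXC0402
SYNEXC0403
SYNEXC0404
SYNEXC0405
SYNEXC0406
SYNEXC0407
SYNEXC0408
SYNEXC0409
SYNEXC0410
SYNEXC0411
SYNEXC0412
SYNEXC0413
SYNEXC0414
SYNEXC0415
SYNEXC0416
SYNEXC0417
SYNEXC0418
SYNEXC0419
SYNEXC0420
SYNEXC0421
SYNEXC0422
SYNEXC0423
SYNEXC0424
SYNEXC0425
SYNEXC0426
SYNEXC0427
SYNEXC0428
SYNEXC0429
SYNEXC0430
SYNEXC0431
SYNEXC0432
SYNEXC0433
SYNEXC0434
SYNEXC0435
SYNEXC0436
SYNEXC0437
SYNEXC0438
SYNEXC0439
SYNEXC0440
SYNEXC0441
SYNEXC0442
SYNEXC0443
SYNEXC0444
SYNEXC0445
SYNEXC0446
SYNEXC0447
SYNEXC0448
SYNEXC0449
SYNEXC0450
SYNEXC0451
SYNEXC0452
SYNEXC0453
SYNEXC0454
SYNEXC0455
SYNEXC0456
SYNEXC0457
SYNEXC0458
SYNEXC0459
SYNEXC0460
SYNEXC0461
SYNEXC0462
SYNEXC0463
SYNEXC0464
SYNEXC0465
SYNEXC0466
SYNEXC0467
SYNEXC0468
SYNEXC0469
SYNEXC0470
SYNEXC0471
SYNEXC0472
SYNEXC0473
SYNEXC0474
SYNEXC0475
SYNEXC0476
SYNEXC0477
SYNEXC0478
SYNEXC0479
SYNEXC0480
SYNEXC0481
SYNEXC0482
SYNEXC0483
SYNEXC0484
SYNEXC0485
SYNEXC0486
SYNEXC0487
SYNEXC0488
SYNEXC0489
SYNEXC0490
SYNEXC0491
SYNEXC0492
SYNEXC0493
SYNEXC0494
SYNEXC0495
SYNEXC0496
SYNEXC0497
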