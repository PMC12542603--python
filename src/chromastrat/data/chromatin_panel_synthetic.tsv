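gene
HMGN1
HMGN2
HMGN3
HMGN4
HMGN5
HMGB1
HMGB2
HMGB3
HMGA1
HMGA2
HMG20A
HMG20B
HMGXB3
HMGXB4
CTCF
CTCFL
RAD21
RAD21L1
SMC1A
SMC1B
SMC2
SMC3
SMC4
SMC5
SMC6
STAG1
STAG2
STAG3
NIPBL
MAU2
WAPL
PDS5A
PDS5B
ESCO1
ESCO2
CDCA5
SGO1
SGO2
NCAPD2
NCAPD3
NCAPG
NCAPG2
NCAPH
NCAPH2
SMARCA1
SMARCA2
SMARCA4
SMARCA5
SMARCAD1
SMARCAL1
SMARCB1
SMARCC1
SMARCC2
SMARCD1
SMARCD2
SMARCD3
SMARCE1
ARID1A
ARID1B
ARID2
ARID3A
ARID3B
ARID3C
ARID4A
ARID4B
ARID5A
ARID5B
PBRM1
BRD1
BRD2
BRD3
BRD4
BRD7
BRD8
BRD9
BRDT
ACTL6A
ACTL6B
DPF1
DPF2
DPF3
PHF10
BCL7A
BCL7B
BCL7C
SS18
SS18L1
BCL11A
BCL11B
CHD1
CHD1L
CHD2
CHD3
CHD4
CHD5
CHD6
CHD7
CHD8
CHD9
HELLS
ATRX
SMCHD1
TTF1
TTF2
INO80
INO80B
INO80C
INO80D
INO80E
ACTR5
ACTR6
ACTR8
YY1
YY2
RUVBL1
RUVBL2
EP400
DMAP1
VPS72
YEATS2
YEATS4
MORF4L1
MORF4L2
MRGBP
SRCAP
TRRAP
BAZ1A
BAZ1B
BAZ2A
BAZ2B
BPTF
RSF1
CECR2
CHRAC1
POLE3
POLE4
ASF1A
ASF1B
CHAF1A
CHAF1B
NAP1L1
NAP1L2
NAP1L3
NAP1L4
NAP1L5
NPM1
NPM2
NPM3
SET
SUPT6H
SUPT16H
SSRP1
HIRA
UBN1
UBN2
CABIN1
DAXX
HJURP
ANP32A
ANP32B
ANP32E
SPTY2D1
NASP
EP300
CREBBP
KAT2A
KAT2B
KAT5
KAT6A
KAT6B
KAT7
KAT8
HAT1
ELP3
ELP4
ELP5
ELP6
CLOCK
NCOA1
NCOA2
NCOA3
TAF1
TAF1L
GTF3C4
HDAC1
HDAC2
HDAC3
HDAC4
HDAC5
HDAC6
HDAC7
HDAC8
HDAC9
HDAC10
HDAC11
SIRT1
SIRT2
SIRT3
SIRT4
SIRT5
SIRT6
SIRT7
EZH1
EZH2
SUZ12
EED
RBBP4
RBBP7
JARID2
AEBP2
PHF1
PHF19
MTF2
EPOP
PALI1
KMT2A
KMT2B
KMT2C
KMT2D
KMT2E
SETD1A
SETD1B
SETD2
SETD3
SETD4
SETD5
SETD6
SETD7
SETDB1
SETDB2
SUV39H1
SUV39H2
EHMT1
EHMT2
SETMAR
NSD1
NSD2
NSD3
DOT1L
SMYD1
SMYD2
SMYD3
SMYD4
SMYD5
PRDM1
PRDM2
PRDM4
PRDM5
PRDM6
PRDM8
PRDM9
PRDM11
PRDM12
PRDM16
ASH1L
ASH2L
WDR5
WDR82
DPY30
RBBP5
MEN1
HCFC1
HCFC2
KMT5A
KMT5B
KMT5C
KDM1A
KDM1B
KDM2A
KDM2B
KDM3A
KDM3B
KDM4A
KDM4B
KDM4C
KDM4D
KDM5A
KDM5B
KDM5C
KDM6A
KDM6B
KDM7A
KDM8
PHF2
PHF8
JMJD1C
JMJD6
RIOX1
RIOX2
HR
DNMT1
DNMT3A
DNMT3B
DNMT3L
TET1
TET2
TET3
MBD1
MBD2
MBD3
MBD4
MBD5
MBD6
MECP2
UHRF1
UHRF2
ZBTB4
ZBTB33
ZBTB38
GADD45A
GADD45B
GADD45G
TDG
AICDA
RING1
RNF2
BMI1
PCGF1
PCGF2
PCGF3
PCGF5
PCGF6
CBX1
CBX2
CBX3
CBX4
CBX5
CBX6
CBX7
CBX8
PHC1
PHC2
PHC3
SCMH1
SCML1
SCML2
SCML4
AUTS2
USP7
USP16
USP21
USP22
BAP1
ASXL1
ASXL2
ASXL3
MYSM1
PR-DUB
LBR
TRIM24
TRIM28
TRIM33
TRIM66
ING1
ING2
ING3
ING4
ING5
PHF21A
SP100
SP110
SP140
SP140L
BRWD1
BRWD3
TAF3
DIDO1
PSIP1
MLLT1
MLLT3
MLLT6
MLLT10
ZMYND8
ZMYND11
GLYR1
MSL1
MSL2
MSL3
KANSL1
KANSL2
KANSL3
MBTD1
L3MBTL1
L3MBTL2
L3MBTL3
L3MBTL4
SFMBT1
SFMBT2
LMNA
LMNB1
LMNB2
BANF1
EMD
TMPO
SUN1
SUN2
SYNE1
SYNE2
TOR1AIP1
PRR14
LEMD2
LEMD3
TOP1
TOP1MT
TOP2A
TOP2B
TOP3A
TOP3B
H2AZ1
H2AZ2
MACROH2A1
MACROH2A2
H3-3A
H3-3B
CENPA
H2AX
H1-0
H1-1
H1-2
H1-3
H1-4
H1-5
H1-10
DEK
PHB
PHB2
MTA1
MTA2
MTA3
GATAD2A
GATAD2B
CDK2AP1
PWWP2A
PWWP2B
SATB1
SATB2
SAFB
SAFB2
MATR3
HNRNPU
NCL
PARP1
PARP2
MACROD1
MACROD2
EPC1
EPC2
MEAF6
BRPF1
BRPF3
JADE1
JADE2
JADE3
TADA1
TADA2A
TADA2B
TADA3
ATXN7
ATXN7L3
ENY2
SUPT3H
SUPT7L
SUPT20H
TAF5L
TAF6L
ZZZ3
SGF29
SIN3A
SIN3B
SAP18
SAP30
SAP30L
SAP130
SUDS3
BRMS1
BRMS1L
NCOR1
NCOR2
TBL1X
TBL1XR1
GPS2
RCOR1
RCOR2
RCOR3
GSE1
GFI1
GFI1B
SPEN
SKI
SKIL
NRIP1
ADNP
WIZ
CTBP1
CTBP2
ZNF143
MAZ
MECOM
SALL4
IKZF1
IKZF2
IKZF3
BTAF1
HLTF
SHPRH
RAD54L
RAD54B
RAD54L2
ERCC6
ERCC6L
ERCC6L2
ALC1
CHD1L2
BAZ2C
MORC1
MORC2
MORC3
MORC4
BEND3
TONSL
HP1BP3
UBE2A
UBE2B
RNF20
RNF40
UBE2E1
PCGF4
NFRKB
TFPT
UCHL5
MCRS1
ZNHIT1
ZNHIT2
ZNHIT3
ZNHIT6
CDYL
CDYL2
CDY1
MPP8
MPHOSPH8
TASOR
FAM208B
PPHLN1
SETX
SIRT1L
BANP
BEND5
BEND6
BEND7
THAP1
THAP7
THAP11
SPOC1
PHF13
PHF6
PHF7
PHF12
PHF14
PHF20
PHF20L1
PHF23
ZMYM2
ZMYM3
ZMYM4
RERE
ARID4C
POGZ
AHDC1
ADNP2
CHAMP1
ZNF280C
ZNF516
ZNF532
NUCKS1
PTMA
PTMS
PARPBP
TIMELESS
TIPIN
BCOR
BCORL1
KDM2AL
SKP1
CUL4A
CUL4B
DDB1
DCAF1
VPRBP
MTA1L
RBM14
SPINDOC
SPIN1
SPIN2A
SPIN2B
SPIN3
SPIN4
GLTSCR1
GLTSCR1L
BICRA
BICRAL
BRD4L
SYNCR0001
SYNCR0002
SYNCR0003
SYNCR0004
SYNCR0005
SYNCR0006
SYNCR0007
SYNCR0008
SYNCR0009
SYNCR0010
SYNCR0011
SYNCR0012
SYNCR0013
SYNCR0014
SYNCR0015
SYNCR0016
SYNCR0017
SYNCR0018
SYNCR0019
SYNCR0020
SYNCR0021
SYNCR0022
SYNCR0023
SYNCR0024
SYNCR0025
SYNCR0026
SYNCR0027
SYNCR0028
SYNCR0029
SYNCR0030
SYNCR0031
SYNCR0032
SYNCR0033
SYNCR0034
SYNCR0035
SYNCR0036
SYNCR0037
SYNCR0038
SYNCR0039
SYNCR0040
SYNCR0041
SYNCR0042
SYNCR0043
SYNCR0044
SYNCR0045
SYNCR0046
SYNCR0047
SYNCR0048
SYNCR0049
SYNCR0050
SYNCR0051
SYNCR0052
SYNCR0053
SYNCR0054
SYNCR0055
SYNCR0056
SYNCR0057
SYNCR0058
SYNCR0059
SYNCR0060
SYNCR0061
SYNCR0062
SYNCR0063
SYNCR0064
SYNCR0065
SYNCR0066
SYNCR0067
SYNCR0068
SYNCR0069
SYNCR0070
SYNCR0071
SYNCR0072
SYNCR0073
SYNCR0074
SYNCR0075
SYNCR0076
SYNCR0077
SYNCR0078
SYNCR0079
SYNCR0080
SYNCR0081
SYNCR0082
SYNCR0083
SYNCR0084
SYNCR0085
SYNCR0086
SYNCR0087
SYNCR0088
SYNCR0089
SYNCR0090
SYNCR0091
SYNCR0092
SYNCR0093
SYNCR0094
SYNCR0095
SYNCR0096
SYNCR0097
SYNCR0098
SYNCR0099
SYNCR0100
SYNCR0101
SYNCR0102
SYNCR0103
SYNCR0104
SYNCR0105
SYNCR0106
SYNCR0107
SYNCR0108
SYNCR0109
SYNCR0110
SYNCR0111
SYNCR0112
SYNCR0113
SYNCR0114
SYNCR0115
SYNCR0116
SYNCR0117
SYNCR0118
SYNCR0119
SYNCR0120
SYNCR0121
SYNCR0122
SYNCR0123
SYNCR0124
SYNCR0125
SYNCR0126
SYNCR0127
SYNCR0128
SYNCR0129
SYNCR0130
SYNCR0131
SYNCR0132
SYNCR0133
SYNCR0134
SYNCR0135
SYNCR0136
SYNCR0137
SYNCR0138
SYNCR0139
SYNCR0140
SYNCR0141
SYNCR0142
SYNCR0143
SYNCR0144
SYNCR0145
SYNCR0146
SYNCR0147
SYNCR0148
SYNCR0149
SYNCR0150
SYNCR0151
SYNCR0152
SYNCR0153
SYNCR0154
SYNCR0155
SYNCR0156
SYNCR0157
SYNCR0158
SYNCR0159
SYNCR0160
SYNCR0161
SYNCR0162
SYNCR0163
SYNCR0164
SYNCR0165
SYNCR0166
SYNCR0167
SYNCR0168
SYNCR0169
SYNCR0170
SYNCR0171
SYNCR0172
SYNCR0173
SYNCR0174
SYNCR0175
SYNCR0176
SYNCR0177
SYNCR0178
SYNCR0179
SYNCR0180
SYNCR0181
SYNCR0182
SYNCR0183
SYNCR0184
SYNCR0185
SYNCR0186
SYNCR0187
SYNCR0188
SYNCR0189
SYNCR0190
SYNCR0191
SYNCR0192
SYNCR0193
SYNCR0194
SYNCR0195
SYNCR0196
SYNCR0197
SYNCR0198
SYNCR0199
SYNCR0200
SYNCR0201
SYNCR0202
SYNCR0203
SYNCR0204
SYNCR0205
SYNCR0206
SYNCR0207
SYNCR0208
SYNCR0209
SYNCR0210
SYNCR0211
SYNCR0212
SYNCR0213
SYNCR0214
SYNCR0215
SYNCR0216
SYNCR0217
SYNCR0218
SYNCR0219
SYNCR0220
SYNCR0221
SYNCR0222
SYNCR0223
SYNCR0224
SYNCR0225
SYNCR0226
SYNCR0227
SYNCR0228
SYNCR0229
SYNCR0230
SYNCR0231
SYNCR0232
SYNCR0233
SYNCR0234
SYNCR0235
SYNCR0236
SYNCR0237
SYNCR0238
SYNCR0239
SYNCR0240
SYNCR0241
SYNCR0242
SYNCR0243
SYNCR0244
SYNCR0245
SYNCR0246
SYNCR0247
SYNCR0248
SYNCR0249
SYNCR0250
SYNCR0251
SYNCR0252
SYNCR0253
SYNCR0254
SYNCR0255
SYNCR0256
SYNCR0257
SYNCR0258
SYNCR0259
SYNCR0260
SYNCR0261
SYNCR0262
SYNCR0263
SYNCR0264
SYNCR0265
SYNCR0266
SYNCR0267
SYNCR0268
SYNCR0269
SYNCR0270
SYNCR0271
SYNCR0272
SYNCR0273
SYNCR0274
SYNCR0275
SYNCR0276
SYNCR0277
SYNCR0278
SYNCR0279
SYNCR0280
SYNCR0281
SYNCR0282
SYNCR0283
SYNCR0284
SYNCR0285
SYNCR0286
SYNCR0287
SYNCR0288
SYNCR0289
SYNCR0290
SYNCR0291
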