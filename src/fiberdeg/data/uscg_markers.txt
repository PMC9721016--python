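# Default universal single-copy gene (USCG) marker family IDs used for
# copy-number normalization: 76 COG families (ribosomal proteins, tRNA
# synthetases, translation/transcription machinery) that are present in a
# single copy in (nearly) every bacterial genome. Marker protein sequences
# are user-supplied; only the family IDs ship with the package.
COG0008
COG0012
COG0013
COG0016
COG0017
COG0018
COG0030
COG0048
COG0049
COG0050
COG0051
COG0052
COG0060
COG0072
COG0080
COG0081
COG0085
COG0086
COG0087
COG0088
COG0089
COG0090
COG0091
COG0092
COG0093
COG0094
COG0096
COG0097
COG0098
COG0099
COG0100
COG0102
COG0103
COG0124
COG0130
COG0143
COG0162
COG0164
COG0172
COG0173
COG0180
COG0184
COG0185
COG0186
COG0187
COG0193
COG0197
COG0198
COG0199
COG0200
COG0201
COG0202
COG0203
COG0215
COG0216
COG0221
COG0222
COG0227
COG0228
COG0230
COG0231
COG0233
COG0244
COG0250
COG0255
COG0256
COG0261
COG0264
COG0267
COG0268
COG0290
COG0291
COG0292
COG0441
COG0442
COG0495
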