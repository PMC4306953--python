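# Published relative 13C enrichment ratios for 17-chloroakaeolide, one row
# per carbon and feeding experiment (pass-through ratio form; raw
# intensities were not published). C-2 is the designated unlabeled
# reference. Positions 12 and 15 overlap at 34.7 ppm in the spectrum; the
# bold-type enhancement is printed on the position-12 row although the
# incorporation argument ascribes it to C-15 (the C-21/C-12/C-11 fragment
# is propionate-derived). The table is transcribed as printed.
position,shift_ppm,experiment,labeled_intensity,unlabeled_intensity,ratio
1,14.5,acetate_1_13C,,,1.01
2,19.0,acetate_1_13C,,,1.00
3,28.8,acetate_1_13C,,,1.00
4,46.8,acetate_1_13C,,,0.99
5,75.4,acetate_1_13C,,,5.01
6,43.5,acetate_1_13C,,,1.14
7,203.1,acetate_1_13C,,,1.17
8,138.9,acetate_1_13C,,,0.94
9,140.6,acetate_1_13C,,,4.60
10,69.0,acetate_1_13C,,,1.04
11,84.1,acetate_1_13C,,,0.96
12,34.7,acetate_1_13C,,,4.88
13,49.1,acetate_1_13C,,,0.99
14,83.1,acetate_1_13C,,,0.99
15,34.7,acetate_1_13C,,,1.00
16,30.1,acetate_1_13C,,,1.00
17,63.7,acetate_1_13C,,,0.96
18,164.5,acetate_1_13C,,,4.79
19,196.4,acetate_1_13C,,,4.41
20,14.5,acetate_1_13C,,,1.01
21,25.1,acetate_1_13C,,,1.00
22,14.6,acetate_1_13C,,,1.01
1,14.5,acetate_2_13C,,,0.88
2,19.0,acetate_2_13C,,,1.00
3,28.8,acetate_2_13C,,,1.69
4,46.8,acetate_2_13C,,,4.44
5,75.4,acetate_2_13C,,,1.06
6,43.5,acetate_2_13C,,,4.83
7,203.1,acetate_2_13C,,,2.11
8,138.9,acetate_2_13C,,,0.77
9,140.6,acetate_2_13C,,,1.02
10,69.0,acetate_2_13C,,,4.47
11,84.1,acetate_2_13C,,,1.60
12,34.7,acetate_2_13C,,,1.03
13,49.1,acetate_2_13C,,,1.61
14,83.1,acetate_2_13C,,,0.90
15,34.7,acetate_2_13C,,,1.03
16,30.1,acetate_2_13C,,,4.33
17,63.7,acetate_2_13C,,,3.77
18,164.5,acetate_2_13C,,,0.94
19,196.4,acetate_2_13C,,,1.02
20,14.5,acetate_2_13C,,,0.88
21,25.1,acetate_2_13C,,,0.82
22,14.6,acetate_2_13C,,,0.88
1,14.5,propionate_1_13C,,,0.83
2,19.0,propionate_1_13C,,,1.00
3,28.8,propionate_1_13C,,,32.90
4,46.8,propionate_1_13C,,,0.99
5,75.4,propionate_1_13C,,,0.81
6,43.5,propionate_1_13C,,,0.90
7,203.1,propionate_1_13C,,,40.33
8,138.9,propionate_1_13C,,,0.58
9,140.6,propionate_1_13C,,,0.84
10,69.0,propionate_1_13C,,,0.61
11,84.1,propionate_1_13C,,,30.19
12,34.7,propionate_1_13C,,,0.87
13,49.1,propionate_1_13C,,,31.63
14,83.1,propionate_1_13C,,,0.94
15,34.7,propionate_1_13C,,,0.87
16,30.1,propionate_1_13C,,,1.02
17,63.7,propionate_1_13C,,,1.12
18,164.5,propionate_1_13C,,,0.79
19,196.4,propionate_1_13C,,,1.07
20,14.5,propionate_1_13C,,,0.83
21,25.1,propionate_1_13C,,,0.99
22,14.6,propionate_1_13C,,,0.83
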