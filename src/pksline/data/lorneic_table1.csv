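# Published relative 13C enrichment ratios for lorneic acid A, one row per
# carbon and feeding experiment (pass-through ratio form). C-16 is the
# designated unlabeled reference carbon.
position,shift_ppm,experiment,labeled_intensity,unlabeled_intensity,ratio
1,177.7,acetate_1_13C,,,7.25
2,38.3,acetate_1_13C,,,1.04
3,121.8,acetate_1_13C,,,6.71
4,131.9,acetate_1_13C,,,0.99
5,131.7,acetate_1_13C,,,6.53
6,126.4,acetate_1_13C,,,0.97
7,127.8,acetate_1_13C,,,1.03
8,137.3,acetate_1_13C,,,0.93
9,127.0,acetate_1_13C,,,6.49
10,136.1,acetate_1_13C,,,0.80
11,127.4,acetate_1_13C,,,6.13
12,133.7,acetate_1_13C,,,0.90
13,33.0,acetate_1_13C,,,6.35
14,31.6,acetate_1_13C,,,1.02
15,22.3,acetate_1_13C,,,6.32
16,13.9,acetate_1_13C,,,1.00
17,21.2,acetate_1_13C,,,1.01
1,177.7,propionate_1_13C,,,0.88
2,38.3,propionate_1_13C,,,1.02
3,121.8,propionate_1_13C,,,1.03
4,131.9,propionate_1_13C,,,1.01
5,131.7,propionate_1_13C,,,0.83
6,126.4,propionate_1_13C,,,1.01
7,127.8,propionate_1_13C,,,42.61
8,137.3,propionate_1_13C,,,0.73
9,127.0,propionate_1_13C,,,1.13
10,136.1,propionate_1_13C,,,0.81
11,127.4,propionate_1_13C,,,1.13
12,133.7,propionate_1_13C,,,1.00
13,33.0,propionate_1_13C,,,1.07
14,31.6,propionate_1_13C,,,1.00
15,22.3,propionate_1_13C,,,1.04
16,13.9,propionate_1_13C,,,1.00
17,21.2,propionate_1_13C,,,0.99
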