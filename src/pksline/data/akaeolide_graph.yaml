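# Carbon skeleton of akaeolide / 17-chloroakaeolide (C-C bonds only;
# the lactone and ether oxygens are not part of the graph). The chain
# starts at the C-16 methyl (terminal_hint) and walks
# 16-15 | 14-13(+22) | 12-11(+21) | 10-9 | 8-7(+20) | 6-5 | 4-19(+3-2-1) |
# 17-18; the 16-17 bond closes the 15-membered carbocycle and is the
# post-assembly bond. The assignment of the side carbons (propyl 3-2-1 on
# C-4, methyls 22/21/20 on C-14/C-12/C-8) follows the published
# incorporation map; where the text underdetermines it, tests assert unit
# counts and the anomalous bond, not the full atom-to-unit map.
nodes: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19,
        20, 21, 22]
bonds:
- [16, 15]
- [15, 14]
- [14, 13]
- [13, 12]
- [12, 11]
- [11, 10]
- [10, 9]
- [9, 8]
- [8, 7]
- [7, 6]
- [6, 5]
- [5, 4]
- [4, 19]
- [19, 17]
- [17, 18]
- [14, 22]
- [12, 21]
- [8, 20]
- [4, 3]
- [3, 2]
- [2, 1]
- [16, 17]
terminal_hint: 16
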