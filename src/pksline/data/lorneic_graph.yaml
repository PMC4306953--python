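# Carbon skeleton of the lorneic acid A backbone as assembled (C-C bonds
# only): a linear 16-carbon chain from the C-16 methyl (terminal_hint) to
# the C-1 carboxyl carbon, with the C-17 methyl branch on C-8.
nodes: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17]
bonds:
- [1, 2]
- [2, 3]
- [3, 4]
- [4, 5]
- [5, 6]
- [6, 7]
- [7, 8]
- [8, 9]
- [9, 10]
- [10, 11]
- [11, 12]
- [12, 13]
- [13, 14]
- [14, 15]
- [15, 16]
- [8, 17]
terminal_hint: 16
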