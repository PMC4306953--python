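# Akaeolide PKS cluster fixture: one loading module plus seven extension
# modules. AT signature tokens encode the annotated substrates
# (HAFH=malonyl, YASH=methylmalonyl, HASH=alkylmalonyl, here propylmalonyl
# C5); the DH domains of modules 3 and 6 are annotated inactive, so those
# modules act as KR-only and leave hydroxyls.
#
# Stereo bookkeeping: the published carbon-level verdicts are hydroxyls
# C-5 (S) and C-11 (S) from B1-type KRs, propyl at C-4 (R), and methyl at
# C-12 (S) from the ER. Under the beta-processing convention used by the
# assembler (module i reduces C1 of unit i-1) the KR writing the C-11
# hydroxyl sits in module 3, although the source annotation counts it with
# module 2; the discrepancy is in module numbering only, the carbon-level
# outcome is identical. KR fingerprints on modules 1 and 4 are not stated
# in the annotation; B1 is used so the enoyl pairs default to trans.
id: akaeolide
compound_hint: akaeolide
modules:
- index: 0
  loading: true
  domains:
  - {kind: AT, signature: HAFH}
  - {kind: ACP}
- index: 1            # methylmalonyl (C3); DH+KR -> enoyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: YASH}
  - {kind: DH}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 2            # methylmalonyl (C3); DH+ER+KR -> methylene, alpha-methyl S
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: YASH}
  - {kind: DH}
  - {kind: ER, signature: Y}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 3            # malonyl (C2); DH inactive, KR B1 -> hydroxyl (S)
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH, active: false}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 4            # methylmalonyl (C3); DH+KR -> enoyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: YASH}
  - {kind: DH}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 5            # malonyl (C2); no reductive domains -> ketone
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: ACP}
- index: 6            # propylmalonyl (C5); DH inactive, KR B1 -> hydroxyl (S)
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HASH}
  - {kind: DH, active: false}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 7            # malonyl (C2); no reductive domains -> ketone
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: ACP}
  - {kind: TE}
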