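# Lorneic acid PKS cluster fixture: one loading module (acetyl starter)
# plus seven extension modules. Modules 1, 2 and 4 carry the full DH+ER+KR
# set; modules 3, 5, 6 and 7 carry DH+KR. All KRs are B-type, so every
# enoyl pair in the assembled polyene is trans. The ER of module 4 is
# annotated active here; the polyolefinic intermediate scenario in which it
# is unfunctional is obtained by toggling it off (see datasets loader).
id: lorneic
compound_hint: lorneic acid A
modules:
- index: 0
  loading: true
  domains:
  - {kind: AT, signature: ACET}
  - {kind: ACP}
- index: 1            # malonyl; DH+ER+KR -> methylene
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH}
  - {kind: ER, signature: Y}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 2            # malonyl; DH+ER+KR -> methylene
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH}
  - {kind: ER, signature: Y}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 3            # malonyl; DH+KR -> trans enoyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 4            # methylmalonyl; DH+ER+KR -> methylene, alpha-methyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: YASH}
  - {kind: DH}
  - {kind: ER, signature: Y}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 5            # malonyl; DH+KR (B-type) -> trans enoyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 6            # malonyl; DH+KR -> trans enoyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
- index: 7            # malonyl; DH+KR -> trans enoyl
  loading: false
  domains:
  - {kind: KS}
  - {kind: AT, signature: HAFH}
  - {kind: DH}
  - {kind: KR, kr_fingerprint: B1}
  - {kind: ACP}
  - {kind: TE}
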