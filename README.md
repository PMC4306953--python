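# pksline

Modular type I polyketide synthase (PKS) product prediction and
¹³C precursor-unit tiling.

The package implements two independent inference routes for a polyketide
natural product and reconciles them:

1. **Cluster → product.** A declarative description of a PKS cluster
   (ordered modules with typed domains) is turned into the predicted
   *linear* polyketide: acyltransferase signature tokens select the
   starter/extender substrates (malonyl C₂, methylmalonyl C₃,
   alkylmalonyl C₂₊ₙ), and each module's active reductive domains
   (KR / DH / ER) fix the final oxidation state of the β-carbon present at
   its condensation (ketone → hydroxyl → enoyl → methylene), including
   stereo descriptors from KR fingerprint types and ER classes, and
   double-bond geometry from the KR family.
2. **Feeding data → tiling.** Per-carbon ¹³C enrichment ratios from
   precursor-feeding NMR tables are classified against a threshold, and a
   backtracking search partitions the compound's carbon bond graph into a
   starter unit plus head-to-tail extender units consistent with the label
   positions. Bonds that no head-to-tail decomposition can use are flagged
   **anomalous** — they must have formed after chain assembly.

A consistency report compares the two unit sequences position by position.
Seeded generators for clusters, products, graphs and noisy enrichment
tables make the whole pipeline testable offline.

## Command line

```sh
# predicted linear product of a cluster (YAML per-carbon records + SMILES)
pksline predict --cluster cluster.yaml --out product.yaml

# enrichment ratios and enriched-carbon calls from a table CSV
pksline enrich --table table.csv --reference 2 --threshold 3.0

# unit tiling of a carbon graph from enrichment calls
pksline tile --graph graph.yaml --table table.csv --reference 2

# full reconciliation of both routes
pksline check --cluster cluster.yaml --graph graph.yaml \
              --table table.csv --reference 2

# seeded synthetic inputs (cluster, graph, tables, ground truth)
pksline simulate --seed 7 --n-modules 5 --inject-bond --out simdir/
```

`--rules` accepts a YAML rule config overriding the built-in tables
(AT signature → substrate, KR fingerprint → stereo descriptors,
ER class → α-methyl descriptor, KR family → double-bond geometry,
enrichment threshold). Analysis commands are deterministic; only
`simulate` consumes a seed.

## File formats

* **Cluster YAML** — `id`, optional `compound_hint`, and `modules`: each
  with `index` (0 = loading module), `loading`, and ordered `domains` of
  `kind` ∈ {KS, AT, KR, DH, ER, ACP, TE} with optional `signature`,
  `active: false` and `kr_fingerprint`. See
  `src/pksline/data/akaeolide_cluster.yaml`.
* **Enrichment CSV** — header
  `position,shift_ppm,experiment,labeled_intensity,unlabeled_intensity,ratio`;
  either both intensities or a precomputed ratio per row. The ratio of
  carbon *c* is `(L_c/U_c) / (L_ref/U_ref)` (scale invariant, exactly 1 at
  the reference carbon); published tables ship ratios and pass through
  renormalized.
* **Graph YAML** — `nodes`, `bonds` (unordered pairs), optional
  `terminal_hint` naming the chain-start methyl carbon.

## Worked examples

Two fully worked compounds ship in `src/pksline/data/`: **akaeolide**
(22 carbons; the tiling flags exactly the C16–C17 bond as post-assembly)
and **lorneic acid A** (17 carbons; a fully consistent linear assignment).
`pksline check` on either reproduces the published unit sequences.

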