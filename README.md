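# famspace

Sequence-space analysis of protein families, built around the question of
how a bacterial Cdc48-like AAA+ ATPase relates to its eukaryotic and
archaeal relatives: which alignment positions distinguish the families
(typically the N-terminal adaptor-binding domains) and which are
invariant (the Walker A/B boxes of the ATPase modules)? The package
implements the full computational side of such a study as a reusable,
tested pipeline:

- **Rank-encoded MSA PCA** — every aligned residue is replaced by the
  occurrence rank of its symbol within its column (most frequent = rank 1,
  ties broken alphabetically); PCA of the centred rank matrix yields
  per-sequence scores that cluster by family and per-column loadings that
  point at the discriminating positions.
- **Conservation mapping** — columns are classified *variable* /
  *conserved* / *intermediate* at 30% / 10% of the maximal component
  loading, exportable as per-residue structure annotations; per-column
  sequence-logo information content `IC = log2 20 − H` in bits, with an
  optional small-sample correction.
- **Gene co-occurrence** — 2×2 contingency and one-sided Fisher exact
  test for claims like "the ATPase gene occurs only in genomes that also
  encode the 20S proteasome subunits".
- **Biochemistry** — Hill-equation fits
  `y = U + (B − U)·S^h/(Kd^h + S^h)` of binding titrations; ATP turnover
  from the NADH-coupled assay (ε₃₄₀ = 6.22 mM⁻¹ cm⁻¹); assembled-ring
  fraction from integrated size-exclusion peaks.
- **Differential LFQ proteomics** — per-protein log2 fold changes and
  t-test p-values across replicate groups, volcano classification at
  fold change ≥ 1.5 and p < 0.05, and COG-class summaries (class S
  excluded).
- **Seeded simulators** for every input type, each emitting ground truth
  alongside the data, so the whole pipeline is testable offline.

## Worked example

Simulate a three-family alignment (60 sequences × 300 columns; family
divergence confined to columns 1–90, Walker-like motifs conserved
downstream), run the rank-PCA, and classify positions from the PC2
loadings:

```sh
$ famspace simulate msa --seed 1 --out msa
$ famspace pca --alignment msa/families.fasta --labels msa/labels.tsv \
    -k 2 --scores-out scores.tsv --loadings-out loadings.tsv \
    --variance-out variance.tsv
$ head -4 scores.tsv
id	family	PC1	PC2
family1_seq1	family1	5.754566092343436	-0.8387246221907642
family1_seq2	family1	7.231733559016426	-0.19390128066997828
family1_seq3	family1	5.800888435512102	-1.8486757224987704
$ famspace classify --loadings loadings.tsv --component 2 --out positions.tsv
```

The first two components carry 11.3% and 8.5% of the rank variance and
separate the three families cleanly (silhouette 0.79 over PC1–2). Of the
58 columns classified *variable*, 91% lie inside the simulated
family-divergent region — the analysis recovers, from sequence data
alone, that the variable region (not the conserved ATPase-module
positions, 168 of which classify *conserved*) is what distinguishes the
families.

Fit a simulated binding titration (1.5× dilution series, 0.09–3.5 µM,
generated with Kd = 0.36 µM, h = 2, 1% noise) and compute an ATPase
turnover:

```sh
$ famspace simulate curve --seed 1 --out .
$ famspace hillfit --curve mst.tsv --out fit.json
Kd = 0.3658 uM, h = 2.03 (converged=True)
$ famspace atpase --slope -0.00622 --path-cm 1 --enzyme-um 0.25
4 ATP min^-1 complex^-1
```

A ΔA₃₄₀ of −0.00622 min⁻¹ over a 1 cm path is 1 µM NADH consumed per
minute, i.e. 4 ATP min⁻¹ per hexamer at 0.25 µM complex.

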