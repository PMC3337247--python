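# lantimine

Lanthipeptide (type AI lantibiotic) locus mining and product-mass inference.

Ribosomally synthesized and posttranslationally modified peptides (RiPPs) of
the lanthipeptide class are made as a precursor **LanA** = leader peptide +
core peptide. A LanB-like dehydratase converts core Ser/Thr to Dha/Dhb (each
dehydration removes one water, −18.02 Da on the average scale), a LanC-like
cyclase forms the thioether rings, and proteolysis removes the leader. When a
strain secretes a *family* of such products, low-resolution ESI-MS plus an
N-terminal Edman read are often all the data available — and they are enough
to tie every product back to one precursor gene.

`lantimine` implements that inference chain as a reusable library + CLI:

1. **mining** — six-frame ORF calling on raw DNA, scanning translations for
   the conserved LanC motifs (GxxHG, WCxG, CHG with invariant His/Cys), the
   Walker-A box of ABC transporters, and the FDL[DN] leader motif of type AI
   precursors; role-annotated ORFs are grouped into cyclase-anchored clusters.
2. **masses** — peptide mass arithmetic (average or monoisotopic) and ESI
   deconvolution. For an ion [M+zH]^z+ at position *m/z*,
   `M = z·(m/z − m_proton)`; signals of one species across charge states are
   combined into a consensus neutral mass, with the integer report taken as
   the truncated mass from the highest charge state.
3. **matching** — enumerate cleavage sites around the leader motif, dehydrate
   each candidate core *k* times (`mass − k·18.015`), rank hypotheses by mass
   error against each observed product, apply Edman N-terminal constraints,
   read truncation ladders (inter-product differences matching single residue
   masses), and test whether the product family is consistent with
   independent protease cuts and/or stepwise N-terminal trimming.
4. **synth** — seeded generators of gene clusters, precursors, product
   ladders and noisy (m/z, z) signal lists with known ground truth, so every
   stage is testable without downloads.

## Worked example

The four secreted products of the modelled locus give paired 3+/4+ ESI
signals (shipped in `data/elgicin_observed_signals.tsv`). Running
`python examples/deconvolute_product_masses.py`:

```
product        consensus (Da)   reported (Da)
elgicin_AI          4535.95           4536
elgicin_AII         4593.96           4593
elgicin_B           4706.75           4706
elgicin_C           4821.20           4820

mass ladder (adjacent differences and residue calls):
  4536 -> 4593: +57 Da  = G
  4593 -> 4706: +113 Da  = I/L
  4706 -> 4820: +114 Da  = N
```

The +57/+113/+114 Da steps are the masses of single Gly, Leu(/Ile) and Asn
residues: the products form a truncation ladder from one precursor. Matching
the masses against a synthetic, mass-matched 64-residue stand-in precursor
(`python examples/match_precursor_variants.py`) places all four products at
consecutive cleavage sites 20–23 with eight dehydrations each (the 144 Da
deficit = 8 × 18.015), and an Edman read of `LGDY` pins the major product's
cleavage uniquely after residue 21:

```
product        cleave_after  n_dehydr  delta (Da)  core N-terminus
elgicin_AI               23         8      -0.16  DYTTSCHK...
elgicin_AII              22         8       0.80  GDYTTSCH...
elgicin_B                21         8       0.43  LGDYTTSC...
elgicin_C                20         8       0.78  NLGDYTTS...
```

`python examples/mine_synthetic_locus.py` shows the genomic side: a
generated five-gene locus is mined back from raw DNA, recovering the strand
pattern `-++++`, the 4-bp same-strand gene overlap and the FDL[DN]-leader
precursor.

The same stages are available from a shell:

```sh
lantimine simulate --seed 7 --out-dir work/   # synthetic locus + signals + truth
lantimine mine work/cluster.fna --out-dir work/       # GFF3 + cluster summary
lantimine match work/precursor.faa work/signals.tsv --nterm LGDY --out-dir work/
lantimine run --seed 7 --out-dir work/        # all three chained
```

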