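# Methods

## Model and procedure

`lantimine` treats a lanthipeptide product family as the observable output of
three deterministic transformations of one precursor peptide:

1. **Leader proteolysis** at an inter-residue position *p* ("cleavage after
   residue *p*"), leaving the suffix as the core peptide. Leader-protease
   sites cluster a few residues C-terminal of the conserved FDL[DN] box, so
   by default candidate sites are enumerated in a 10-position window
   centred on the last residue of that motif (the full sequence when no
   motif is present).
2. **Dehydration** of *k* core Ser/Thr residues, each removing exactly one
   water. Only the count *k* is modelled — integer-Da mass data cannot
   localise which Ser/Thr are modified — and *k* is capped by the core's
   Ser+Thr count. Thioether cyclisation is mass-neutral and therefore
   invisible to this model.
3. **Electrospray ionisation** as [M+zH]^z+ ions: an observed signal
   (m/z, z) deconvolves to `M = z·(m/z − 1.007276)`.

A hypothesis (p, k) matches an observed neutral mass when
`|M_obs − (mass(core_p) − k·m_water)| ≤ tol`. Competing hypotheses are
ranked by absolute mass error, then fewer dehydrations, then the more
C-terminal site; near-ties are all reported so that orthogonal evidence
(an Edman N-terminal read) can resolve them, exactly as it does in
practice.

## Mass conventions

* **Average vs monoisotopic.** The default scale is *average*: ~4.5 kDa
  peptides measured on an ion trap at two-decimal m/z precision are not
  isotope-resolved, and integer-Da reporting is consistent with average
  masses. Monoisotopic mode is available everywhere (`scale=`).
* **Residue masses** come from the standard amino-acid compositions in
  pyteomics (monoisotopic, and abundance-weighted average). Water:
  18.01056 Da mono / 18.01529 Da average. Proton: 1.007276 Da.
* **Integer reporting rule.** The full-precision consensus mass is the mean
  of per-signal deconvolved masses, but the *integer report* is the
  truncation (floor) of the mass derived from the highest charge state.
  That rule reproduces all four worked-example product masses from their
  4+ ions, whereas rounding, or using the 3+ ions, deviates by 1–2 Da;
  it is a modelling choice for low-resolution instrument reports, and the
  full-precision value is always retained alongside.
* **Tolerances.** Matching tolerance defaults to 1.0 Da (average scale);
  the cross-charge-state consistency window defaults to 3 Da because 3+/4+
  deconvolutions of the same real species disagree by up to ~2 Da at this
  precision. A dehydration-count residual above 2.0 Da flags the estimate
  low-confidence. None of these are fitted; they reflect instrument
  precision.
* **Near-isobars.** `residue_from_delta` reports *every* residue within
  tolerance: Leu/Ile (strictly isobaric) are always co-reported, and pairs
  such as Gln/Lys (0.04 Da apart on the average scale) are automatically
  co-reported at any tolerance ≥ their separation. The package never picks
  a winner the measurement cannot support.

## Mining heuristics

* ORFs are maximal start-to-stop spans in all six frames (standard genetic
  code; starts {ATG, GTG, TTG}; the initiator is reported as Met; default
  minimum 25 aa so the 64-aa precursor is comfortably callable). Internal
  coordinates are 0-based half-open including the stop codon; motif hits
  are 1-based inclusive, matching how protein positions are quoted in the
  literature.
* The cyclase patterns require only the strictly conserved residues
  (G‑x‑x‑H‑G, W‑C‑x‑G, C‑H‑G): genuine LanC instances such as GVSHG violate
  a literal third-position pattern. A protein is cyclase-like only if all
  three motifs occur in N-to-C order.
* Role rules, in priority order: cyclase-like (motif triad); precursor
  (≤ 100 aa with FDL[DN] in the N-terminal half); dehydratase-like
  (≥ 800 aa, not a cyclase); transporter-like (Walker-A box G-x-x-G-x-G-K-[S/T]
  and 400–800 aa — a sequence heuristic, flagged as such in GFF output,
  not a homology call). Everything else is `unknown` and never joins a
  cluster.
* Clusters group role-carrying ORFs whose pairwise gaps are ≤ 2000 bp and
  are reported only when they contain at least one cyclase-like and one
  precursor ORF.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *inference-relevant* features of a real locus
and spectrum set: a five-gene cluster (596/454/625/1037/64 aa) with the
first gene on the minus strand and a same-strand 4-bp overlap between the
third and fourth genes; a 64-aa precursor (21-residue leader carrying
FDL[DN], 43-residue core with ≥ 8 Ser/Thr and ≥ 2 Cys placed deep enough
that N-terminal trimming never removes them); a four-product ladder at
consecutive cleavage sites around the leader/core boundary, each product
dehydrated the same number of times (default 8); and 3+/4+ signals with
Gaussian noise applied in m/z space (instrument-like), not mass space.

Design choices: back-translation draws synonymous codons uniformly (no
codon-usage model — irrelevant to the tested logic); the amino-acid
background is uniform outside planted motifs; intergenic spacers are CTAG
repeats, which contain stop codons in all six frames and no start codons,
pinning called gene boundaries. Because random coding sequence can still
create artifacts — a spurious short ORF that happens to satisfy the
precursor rule, or an in-frame upstream start that would absorb the
4-bp-overlap gene — the cluster generator validates each candidate contig
with the package's own miner and redraws from a derived subseed until the
planted layout is exactly recoverable. This is deterministic per seed
(typically 1–2 draws) and makes exact layout recovery part of the
generator's contract.

What the synthetic data does **not** model: isotope envelopes and peak
shapes (inputs are already-picked signals), retention behaviour, codon
bias, sequencing error, adducts other than protons, or homology detectable
only by alignment. Passing tests therefore demonstrate the correctness of
the deconvolution/matching logic and the motif-based mining rules under
realistic mass noise — not the sensitivity of motif rules against the
diversity of real genomes, which would require curated sequence sets.

## Numerical and degenerate-input choices

* Mass/m/z conversion is exact arithmetic; the round-trip is tested to
  1e-9 Da across charges 1–10.
* `consensus_mass` of conflicting signals (spread beyond the window) raises
  a typed error rather than averaging incompatible species; an empty
  candidate set from `residue_from_delta` is a result ("no single-residue
  explanation"), not an exception.
* Assignment sorting is a total order (error, dehydration count, site), so
  results are invariant to input order; exact ties remain adjacent rows.
* The empty peptide has the mass of water; a cleavage window of width one
  yields exactly one variant; a single matched product yields an
  "indeterminate" processing-route report.

## Problem sizes

The test suite and the acceptance script regenerate everything they
measure: 200 ORF-oracle sequences up to 5 kb, 200 matcher-recovery runs
each at zero and 0.05 Th m/z noise, and 50 full simulate→mine→match
pipelines — sizes at which every property is measured with comfortable
margins while the whole suite runs in a few seconds.

## Known limitations

* Ring topology (which Cys pairs with which Dha/Dhb) and dehydration
  localisation are out of scope; only counts and cleavage positions are
  inferred.
* Role assignment is motif/size-based and intentionally conservative;
  it is not a substitute for homology search on real genomes.
* The ladder reader links only adjacent masses after sorting;
  multi-residue gaps are reported unexplained rather than combinatorially
  decomposed (the decomposition is rarely unique at 1 Da tolerance).
* At integer-mass precision Asn (114.10) and Asp (115.09) differ by less
  than 1.1 Da: a 114 Da ladder step calls Asn at tight tolerance, but the
  package deliberately reports all residues within the user's tolerance
  rather than adjudicating between such near-calls.
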