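# fsindel

Predicts whether a frameshifting (FS) coding indel is **gene-damaging** or
**functionally neutral**. An FS indel (net length not divisible by 3)
scrambles every downstream codon; whether that destroys the gene product
depends mostly on *where* it lands and *how much conserved sequence* it
takes with it. The package provides:

* **genome_model** — domain types (indels, transcript models, conservation
  tracks) and readers/writers for VCF, tab-separated indel tables, GTF/GFF3,
  FASTA, fixed/variable-step wig, bedGraph and per-residue score TSVs.
  Internal coordinates are 0-based half-open; VCF/TSV I/O is 1-based.
* **features** — the four selected features of an FS indel against all
  transcripts of its gene:
  `f14` percent of the gene's conserved DNA bases affected,
  `f5` relative location in the coding sequence (max over transcripts),
  `f18` percent of conserved amino acids lost (max over transcripts),
  `f15` minimum distance to an exon boundary (bp). An open registry allows
  plugging extra named features.
* **rules** — the published four-rule classifier with exact thresholds,
  training counts and confidence scores; first-match classification with a
  configurable fallback for the uncovered gaps; extraction of rule paths
  (with coverage counts) from any trained tree.
* **training** — C4.5-style decision-tree induction (information gain,
  pessimistic confidence pruning), balanced sampling, stratified ten-fold
  cross-validation with the four metrics (sensitivity, specificity,
  precision, accuracy), repeated CV with resampled negatives, and greedy
  forward feature selection with a 0.1 %-improvement stop rule.
* **curation** — dataset filters: one-indel-per-gene (disease mode) /
  pseudogene removal (neutral mode), quality-window filtering, symmetric
  neighbor-distance filtering, and multi-species same-lineage concordance.
* **compensation** — compensatory-indel analysis: single-linkage clustering
  of FS indels within a window, the fraction of clusters whose net size
  restores the reading frame as a function of window size, and exon-versus-
  intron enrichment of frame-restoring pairs.
* **simulate** — synthetic fixtures for everything above: labeled feature
  vectors with the rule structure planted at the published thresholds, toy
  genes with conservation tracks, and clustered indel sets with a
  controlled frame-restoration probability.

## CLI

```sh
fsindel classify --indels calls.vcf --annotation genes.gtf \
    --dna-scores phylop.wig --protein-scores protein_scores.tsv \
    --out predictions.tsv
fsindel train --features labeled.tsv --model-out tree.json --rules-out rules.json
fsindel select-features --features labeled.tsv --out selected.json
fsindel curate --config curate.yaml
fsindel compensation --indels indels.tsv --windows 10,20,50 --out curve.tsv
fsindel af-spectrum --predictions preds.tsv --out spectrum.tsv
fsindel simulate --config sim.yaml --out-dir fixtures/
```

Every subcommand supports `--seed`; each run writes its resolved
configuration to `<output>.config.yaml`, so identical config + seed gives
byte-identical outputs.

## Notes on conventions

* Indels are validated as pure insertions/deletions after trimming shared
  allele prefixes/suffixes; mixed substitutions are rejected.
* "Affected" region of an FS indel = first frameshifted coding base through
  the end of the coding sequence.
* Conservation thresholds are configuration knobs: DNA score >= 1.5 by
  default, protein residues >= the per-protein upper quartile unless an
  explicit threshold is given. Missing conservation scores count as "not
  conserved" but are tallied separately from zero scores.
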