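# Driver knowledge-base fixtures (synthetic stand-ins)

These TSVs stand in for non-redistributable knowledge sources: recurrently
mutated gene lists from iCCA sequencing studies, COSMIC biliary-tract
frequency extracts, the cancer gene census, and SIFT score tables.

* `driver_genes.tsv` — gene symbols with a provenance tag each.
* `known_mutations.tsv` — amino-acid-level known mutations; exact matches make
  a mutation high-confidence, residues within 5 make it putative. The
  proximity anchors here are synthetic: plausible residue positions chosen so
  the curated iCCA driver-call fixture re-derives its documented tiers.
* `sift_scores.tsv` — synthetic SIFT scores (< 0.05 is deleterious).
* `promotions.tsv` — manual-review promotions (gene, aa_change, justification).

Edit or replace these files to run the tiering against a real knowledge base.
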