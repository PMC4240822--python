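# Methods

## Model and assumptions

The cascade targets monogenic, autosomal dominant, fully penetrant disease
in nuclear families: every affected member must carry at least one copy of
the causal allele and every unaffected member none. Presence is defined as
≥1 alt allele — heterozygous and homozygous-alt carriers both pass, since
the segregation rule constrains presence/absence, not zygosity.
Unknown-affection samples are ignored by the filter. These assumptions fail
for reduced penetrance, phenocopies, recessive or X-linked inheritance, and
de novo events; none of those models is implemented.

The three hard filters (panel, segregation, frequency) are pure per-variant
predicates, so they commute — the test suite asserts order independence on
randomized datasets. Consequence, conservation and predictor stages are
advisory annotations: they order and describe candidates but never change
the candidate/excluded verdict. This reflects practice, where a recurrent
mutation is retained as the causal candidate even when prediction tools
score it benign.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 1e-4 | exclusion bound, reading "MAF > 0.01%" literally; the rule is strictly greater-than, so a MAF exactly at the threshold is kept. The worked exclusions span 0.4%–54.69%, so the printed counts are insensitive to any threshold below 0.004. |
| `missing_policy` | `strict` | a missing genotype in any consulted sample fails the variant (favors specificity); `lenient` skips that sample. |
| PolyPhen-2 cutpoints | 0.453 / 0.957 | benign / possibly / probably damaging category floors (HumDiv-style). |
| PON-P2 rule | prob ± SE vs 0.5 | pathogenic or neutral only when the interval clears 0.5; otherwise "unknown". |

MAF is folded (`min(p, 1−p)`): frequency tables report alt-allele counts,
and an alt fraction of 54.69% is a 45.31% minor allele frequency. Variants
absent from the table are novel and treated as MAF 0.

`damaging_count` totals tools voting damaging (SIFT < 0.05, PolyPhen-2
non-benign, PMUT > 0.5, PANTHER subPSEC < −3, PON-P2 pathogenic,
MutPred > 0.5). Candidates sort by damaging count (desc), then MAF (asc,
novel = 0), then genomic coordinate — a deterministic order.

## Coordinates, transcripts and HGVS

VCF and all variant positions are 1-based; BED panel intervals are 0-based
half-open, converted at the read boundary. Only PASS/"." VCF records enter
the cascade. Multi-allelic records are split per alt allele; alleles of a
non-retained alt are recoded as reference in the split record, which keeps
per-(sample, alt) carrier counts exactly conserved.

Transcript models carry exon intervals in transcript orientation, the cDNA
offset of the initiator ATG, and the coding sequence (terminal stop
included). The genomic↔cDNA mapping is exact and bijective over the CDS;
minus-strand transcripts complement alleles before translation. The HGVS
surface covers single-nucleotide CDS substitutions only (`c.<pos><ref>><alt>`,
`p.<Ref><idx><Alt>`, `p.(=)` for synonymous, `p.Met1?` for start-loss);
indel and splice notation are out of scope. Protein numbering uses
initiator-Met = 1; mature-protein renumbering (residue number − 1 after Met
cleavage) is an explicit separate operation, never a silent default.

The packaged CRYGD and GJA8 transcript fixtures anchor the published
genomic↔cDNA coordinate pairs. The printed data fix the amino acids, not
the reference codons, so the fixtures use one synonymous choice (CCA for
Pro24, CTG for Leu7, CAT for His98) and the suite asserts that any
synonymous reference codon yields the identical protein-level call. CRYGD
is modelled plus-strand so the printed position/allele/`c.` triple is
internally consistent; strand handling is exercised by a synthetic
minus-strand transcript in the tests. The fixture coding sequences are
synthetic filler outside the anchored codons — they support coordinate and
codon arithmetic, not sequence-level biology.

Conservation is the fraction of non-reference alignment rows matching the
reference residue at a column, with gaps counted as mismatches
(conservative and deterministic). The packaged alignment windows are
synthetic stand-ins (named `*_synthetic.fa`) that reproduce the reported
pattern — Pro24 poorly conserved, Leu7 and His98 fully conserved — not real
orthologue sequences.

## Synthetic data generator

`simulate_family` emulates the statistical structure the cascade assumes:

- pedigree shapes: `trio` (affected parent, unaffected spouse, affected
  child), `family_b` (five samples, four affected), `family_c` (four
  samples, two affected);
- one planted causal variant in an autosomal panel gene: heterozygous in
  every affected, absent in every unaffected and from the frequency table;
  affected children receive the alt allele from their affected parent, so
  transmission is Mendelian-consistent by construction;
- background variants placed uniformly within panel regions, with
  population frequency drawn from a mixture of a point mass at 0 (novel
  fraction 0.05) and Uniform(0.004, 0.55), matching the ranges seen in
  candidate-panel reviews; founder genotypes are Hardy–Weinberg draws,
  children inherit one allele per parent uniformly;
- optional genotyping noise flips each written allele independently with
  the configured rate;
- identical configurations (including the seed) give byte-identical output
  files.

What the generator does **not** model: linkage disequilibrium (the filters
are single-variant), sequencing depth/quality, population structure,
mosaicism, or locus heterogeneity. Passing recovery tests therefore shows
the cascade's logic is correct under its own assumptions, not that those
assumptions hold for any particular real exome.

The closed-form chance-co-segregation probability (product over consulted
samples of the Hardy–Weinberg carrier/non-carrier probability) treats
family members as independent draws; it slightly misstates within-family
correlation but preserves the ordering that matters — more informative
samples mean fewer false candidates, which the simulation tests confirm.

## Numerical and design choices

- Simulated population tables use AN = 8,600 alleles and AC = round(MAF·AN),
  the resolution of an exome-server frequency listing.
- Recovery experiments derive per-replicate seeds from a `SeedSequence`, so
  replicate streams are independent and reproducible.
- Problem sizes in the default suite: 100 background variants per simulated
  family, 200 replicates for the zero-noise recovery check, 10,000 founders
  for Hardy–Weinberg calibration (within 3 standard errors), exhaustive
  4-state genotype enumeration for pedigrees up to five samples.
- The packaged per-family review table is a synthetic stand-in (named
  `*_synthetic.tsv`) constructed to the published marginal totals — 112
  distinct variants over 32 of 39 genes; per-family 76/73/82; five variants
  without rs identifiers — used to exercise the distinct-variant/gene tally.
- Degenerate inputs: an empty variant list yields an empty trail list; a
  pedigree lacking either affection class is a hard error (the segregation
  filter is undefined); a panel miss, non-coding position or reference
  mismatch during annotation skips the advisory stage for that variant
  rather than failing the run.

## Known limitations

Dominant model only; SNV-only consequence annotation; no per-genotype
quality or depth filtering (the pipeline consumes post-QC calls); the
Novel/Recurrent status column is a lookup against an editable shipped list,
not a database query; per-family variant totals on real exomes depend on
upstream calling and QC choices the pipeline does not control.
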