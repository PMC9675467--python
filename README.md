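# pascrispr

Allele-specific CRISPR/Cas9 design from PAM-altering SNPs, for researchers
working on haplotype-selective silencing of dominant disease alleles
(the motivating case is mutant *HTT* in Huntington's disease).

SpCas9 requires a 5′-NGG-3′ PAM next to its protospacer. A **PAM-altering
SNP (PAS)** is a variant one of whose alleles creates or destroys a PAM
occurrence, so a single guide can cut the chromosome that carries the PAM
and spare the one that does not. `pascrispr` implements the complete
in-silico pipeline around that idea:

- **scan** — classify coding SNVs as `ref_generating`, `alt_generating`,
  `both` or `none` by diffing PAM occurrences under each allele (both
  strands); the tallies always satisfy `ref + alt − both = total`.
- **hapmap** — assign phased chromosomes to named haplotypes by exact
  tag-allele match, take per-haplotype consensus PAS alleles (majority,
  ties to reference), and partition PAS into PAM on **all** / **none** /
  **some** (polymorphic) haplotypes.
- **specificity** — with each subject an ordered (mutant, normal) haplotype
  pair, compute the fraction of subjects whose PAM is mutant-only /
  normal-only / both / neither (the four fractions sum to 1).
- **guide** — 20-nt protospacer immediately 5′ of an allele-exclusive PAM,
  blunt cut 3 nt from the PAM; refuses PAMs present under both alleles.
- **NMD prediction** — apply an indel to a transcript model, translate the
  spliced CDS to the first stop, and predict nonsense-mediated decay iff
  the stop ends ≥ 55 nt upstream of the last exon–exon junction.
- **editqc** — per-allele % edited and in-/out-of-frame fractions from
  classified amplicon reads (indel intersecting cut ± 10 nt; frame by net
  length mod 3).
- **ase / enrich** — per-site two-tailed Student *t* tests of allele counts
  across clone groups with Bonferroni correction per allele class, and
  permutation gene-set enrichment with empirical
  p = (1 + #{null ≥ observed}) / (1 + N).
- **simulate** — seeded generators for every input above with planted
  truth, so the whole chain is testable without downloads.

## Worked example

Run the full synthetic study (a 6-kb, 8-exon gene; 1,000 subjects over 8
haplotypes at realistic frequencies; 10,000 amplicon reads per allele;
12 RNA-seq clones per group):

```sh
pascrispr all --seed 3 --out-dir run1
```

prints

```
simulate: wrote synthetic inputs for seed 3 to run1
scan: 5 coding PAS (4 ref + 2 alt - 1 both)
hapmap: PAM on all/none/some haplotypes: 3/1/1
specificity[pas_000]: mutant-only 23.7% of subjects
guide: 1 design(s) for pas_000 allele G
editqc: mutant 15.95% edited, normal 0.00% edited
ase: significant sites mutant 10/10, normal 0/10
enrich: empirical p = 0.07929 (set 52/16840 genes)
```

Reading the output: the scanner recovers the five planted PAS with the
inclusive tallies 4 + 2 − 1 = 5; exactly one PAS is polymorphic across
haplotypes — its PAM is missing from the most common haplotype, so 23.7% of
subjects carry it on the mutant chromosome only and are eligible for
allele-specific targeting. The guide anchored at that PAM edits 15.95% of
mutant-allele reads and exactly 0% of normal-allele reads (the planted
fractions were 16.07% and 0%). The 10-fold mutant-allele knockdown is
detected at all 10 heterozygous sites after Bonferroni correction while no
normal-allele site moves, and the (unenriched) off-target gene set shows no
permutation enrichment.

Every stage is also runnable on its own files (`pascrispr scan --fasta …
--vcf … --bed …`, etc.) and writes a JSON run report with input checksums,
parameters and the seed. The library API mirrors the stages
(`classify_pas`, `assign_haplotypes`, `mutant_specificity`, `design_guide`,
`predict_ptc_nmd`, `summarize_editing`, `ase_site_test`,
`permutation_enrichment`).

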