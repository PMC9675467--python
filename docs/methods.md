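# Methods

## The problem

Huntington's disease is caused by a dominant expanded CAG repeat in one copy
of *HTT*; one intact copy suffices, so selectively inactivating the mutant
allele is therapeutically attractive. SpCas9 only cuts next to a 5′-NGG-3′
protospacer-adjacent motif (PAM). A single-nucleotide variant one of whose
alleles creates or destroys a PAM occurrence — a **PAM-altering SNP (PAS)** —
therefore lets a single guide RNA cut one chromosome and leave the other
untouched, independent of the disease mutation itself. An out-of-frame indel
at the cut site produces a premature termination codon (PTC) and, if the PTC
is far enough upstream of the last exon–exon junction, nonsense-mediated
decay (NMD) of the mutant transcript.

This package implements the full in-silico chain around that idea:

1. **PAS discovery** (`pamscan`): classify coding SNVs by which allele
   carries exclusive PAM occurrences.
2. **Haplotype PAM map** (`haplotypes`): group phased chromosomes into named
   haplotypes by exact tag-allele match, take per-haplotype consensus PAS
   alleles (majority, ties to reference), and mark each PAS as PAM-present
   on all, none, or some haplotypes.
3. **Diplotype specificity** (`specificity`): with each subject an ordered
   (mutant, normal) haplotype pair, sum diplotype frequencies into the four
   cells mutant-only / normal-only / both / neither; or call subjects
   directly from phased alleles at the PAS.
4. **Guide design and NMD prediction** (`guides`): 20-nt protospacer 5′ of
   the PAM on the PAM strand, blunt cut 3 nt from the PAM; apply an indel to
   a transcript model, translate the spliced CDS to the first stop, and apply
   the junction rule.
5. **Editing quantification** (`editquant`): per-allele % edited and
   in-/out-of-frame fractions from classified amplicon reads.
6. **Expression statistics** (`stats`): per-site two-sample Student t tests
   of allele counts across clone groups with Bonferroni correction per allele
   class, and permutation gene-set enrichment with the +1-corrected
   empirical p.
7. **Synthetic data** (`simulate`): generators for every input above, with
   planted truth for round-trip testing.

## Model and conventions

**PAS classification.** For a biallelic SNV, only PAM windows overlapping the
variant position can differ between alleles; those windows are enumerated
under each allele (both strands; minus strand by reverse-complementing the
window) and diffed at identical (strand, window) coordinates. Classes:
`ref_generating`, `alt_generating`, `both` (each allele carries a window the
other lacks — necessarily different windows), `none`. The inclusive tallies
satisfy `n_ref + n_alt − n_both = n_total`. For NGG, a SNP can only be a PAS
if one allele is G or C; this lemma and full brute-force equivalence are
asserted over random instances in the tests. Coordinates are 0-based
half-open internally and 1-based in every on-disk table and VCF.

**Haplotype assignment** is exact match on tag alleles: a chromosome matching
zero or more than one definition is `unassigned` and excluded from consensus
and frequencies (counts logged). Consensus ties break toward the reference
allele — the data do not determine the choice, and reference is deterministic
and conservative.

**Specificity denominators.** Fractions are over the included
(fully assigned, "common diplotype") universe, renormalized; an option
reports unrenormalized cohort fractions. Diplotypes are ordered pairs:
(A, B) with A mutant is a different diplotype from (B, A).

**Guide geometry.** Protospacer length fixed at 20 nt; cut modeled blunt,
3 nt 5′ of the PAM (between protospacer positions 17|18), used only to
center the editing window. A PAM present under both alleles is refused as
not allele-specific. Discriminating alleles through protospacer mismatches
(rather than PAM presence) is represented only as that refusal: single
protospacer mismatches are tolerated by Cas9 and lose allele specificity.

**NMD rule.** The canonical 50–55-nt junction rule, fixed at 55 nt and
configurable: NMD is predicted iff the first stop codon *ends* at least
55 nt upstream of the last exon–exon junction in spliced coordinates
(54 nt → no NMD; a stop in the last exon is never NMD-prone). A CDS with no
in-frame stop is flagged `nonstop` with no NMD call. Frame class is the net
indel length mod 3. Translation uses the standard codon table (via
Biopython's per-codon translation), checked in the tests against whole-CDS
`Seq.translate` as an independent route.

**Editing window.** A read is edited iff an indel op intersects the closed
window cut ± w, with w = 10 nt by default (no window is dictated by the
underlying experimental design; configurable). Net length is summed over
intersecting ops; substitutions are ignored — treating them as edits would
make the call sensitive to sequencing error. Ambiguous reads (base at the
discriminating site neither linked allele, or deleted) leave every
denominator. Frame percentages are of *edited* reads of that allele and sum
to 100 whenever any exist.

**ASE testing.** Classical pooled-variance Student t (two-tailed) per site,
control vs treated clones, on raw counts as counted reads; Welch and
per-clone library-size normalization are available behind flags. Bonferroni
multiplies by the number of sites within the allele class (mutant and normal
panels are separate families, mirroring the two-panel design of the
underlying experiment). Zero-variance degeneracies: equal constant groups
give t = 0, p = 1; unequal constant groups are flagged degenerate with p
reported as 0 and a warning.

**Permutation enrichment.** Set score = sum of member significance values
(−log10 of an upstream FDR-adjusted p; DGE itself is out of scope and
consumed as input). Null sets are drawn uniformly without replacement
(vectorized via random-key argpartition, chunked to bound memory), and
p = (1 + #{null ≥ observed}) / (1 + N), so the smallest attainable p is
1/(N + 1). Default N = 10,000 — a desk-scale default; the full
million-permutation run is a single argument. Candidate genes outside the
expressed universe are dropped with a logged count before scoring.

## What the synthetic data emulates

Each generator draws from its own stream, `default_rng([seed, crc32(stage)])`,
so stages regenerate independently and a fixed seed is bit-reproducible.

- **Gene**: equal-width exons with introns; CDS starts ATG, stop-free in
  frame, ends TAA. PAS are planted as 7-mer contexts that provably realise
  the intended class and are re-verified with the scanner; a plant that
  cannot realise its class raises naming the position. Default design:
  3 ref-generating + 1 alt-generating + 1 both, 20 non-PAS coding SNPs, and
  one tag SNP per haplotype.
- **Population**: chromosome haplotypes drawn from the configured
  frequencies; the defaults are the eight common *HTT* haplotype frequencies
  observed among 1000 Genomes chromosomes (103, 217, 225, 11, 16, 196, 25,
  794 of 1587 — hap.08-like last and most common). Tag SNPs encode the
  haplotype exactly (assignment round-trips at 100%); PAS alleles follow a
  planted per-haplotype scheme — one PAS polymorphic with its PAM absent
  from the last (hap.08-like) haplotype, one PAM-absent everywhere, the rest
  PAM-present everywhere — with 5% within-haplotype minor-allele noise, a
  mild level that leaves every consensus intact at default cohort sizes.
  Each subject's mutant chromosome carries a CAG-repeat surrogate > 35 (the
  repeat is a label, not realised sequence; only the label matters
  downstream).
- **Amplicon reads**: 10,000 reads/allele; planted edit fractions
  (0.1607, 0) by default — the observed mutant/normal editing of the
  rs363099-style design — with indel lengths from a predominantly
  out-of-frame distribution placed within ±2 nt of the cut.
- **ASE counts**: Poisson counts around a common mean (default 100) with a
  shared lognormal clone-depth factor (sd 0.1); treated-group mutant-allele
  means divided by the allelic fold change (default 10), normal allele
  untouched. n = 12 clones/group, 10 heterozygous sites.
- **Gene scores**: −log10 of uniform draws over a 16,840-gene universe with
  a 52-gene planted set shifted by the enrichment effect (default 0: a
  well-behaved screen with no off-target enrichment).

**What it does not emulate** (hence what green tests do not show about real
data): real human sequence composition and linkage disequilibrium,
sequencing error and alignment artefacts, CAG-repeat instability,
overdispersed RNA-seq count structure beyond a single clone-depth factor,
and correlated gene-gene expression in the enrichment universe.

## Numerical and design choices

- Problem sizes in tests and the acceptance script are desk-scale choices:
  6-kb gene, 1,000 subjects, 10,000 reads/allele, 1,000 null ASE
  simulations, 200 enrichment replicates at 9,999 permutations.
- Specificity fractions must sum to 1 within 1e-9 (enforced at
  construction); haplotype frequency vectors likewise.
- PAM motifs are IUPAC, case-insensitive; ambiguity codes in *references*
  are rejected rather than expanded (human and synthetic references are
  unambiguous).
- Only biallelic SNVs are classified; multiallelic VCF records are
  decomposed into ref/alt pairs on ingest and indels skipped with a logged
  count.
- Deletions spanning a splice junction are rejected by `apply_indel`
  (unsupported rather than silently mis-modelled).
- Degenerate inputs have fixed conventions (documented above) rather than
  NaNs: zero-variance t tests, alleles with no reads (`no_data`), nonstop
  transcripts.

## Known limitations

- NMD prediction implements the junction rule only; known exceptions
  (long 3′ exons, start-proximal PTCs, reinitiation) are not modelled.
- Guide designs carry no on-target efficiency or off-target scores;
  off-target candidate lists are consumed as input to the enrichment stage.
- `subject_eligibility` and the diplotype route agree exactly only when
  every chromosome carries its haplotype's consensus allele; with
  within-haplotype polymorphism the subject-level route is the more faithful
  one.
- The permutation test conditions on the observed score table; it does not
  model inter-gene correlation, so its p is exact only under gene-label
  exchangeability.
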