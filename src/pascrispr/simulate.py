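"""Synthetic inputs for every pipeline stage.

The generator emulates, at desk scale, the study designs the pipeline is
built for: a small multi-exon gene with PAM-altering SNPs planted at known
positions and classes; a phased population structured into named haplotypes
with configurable frequencies (defaults follow the eight common HTT
haplotype frequencies observed in 1000 Genomes chromosomes); subjects each
carrying one mutant (expanded CAG surrogate) and one normal chromosome;
amplicon reads with planted per-allele edit fractions and an indel-length
distribution; per-clone allelic RNA-seq count matrices with a planted
allelic fold-change; and a gene significance table with an optionally
enriched planted set.

Each stage draws from its own pseudo-random stream derived from the master
seed and the stage name, so stages can be regenerated independently and a
fixed seed makes every output bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import PhasedGenotypes
from .haplotypes import HaplotypeDefinition
from .pamscan import PamPattern, Variant, classify_pas
from .transcripts import TranscriptModel


class GenerationError(ValueError):
    """A planted feature could not be realised as requested."""


#: Haplotype frequencies matching the 1000 Genomes chromosome counts of the
#: eight common HTT haplotypes (103, 217, 225, 11, 16, 196, 25, 794 of 1587).
KGP_HAPLOTYPE_COUNTS = (103, 217, 225, 11, 16, 196, 25, 794)
DEFAULT_HAPLOTYPE_FREQS = tuple(c / sum(KGP_HAPLOTYPE_COUNTS) for c in KGP_HAPLOTYPE_COUNTS)

#: Predominantly out-of-frame repair outcomes around a blunt Cas9 cut.
DEFAULT_INDEL_LENGTHS = {-1: 0.55, 1: 0.20, -2: 0.10, -4: 0.05, -3: 0.07, 3: 0.03}

#: CAG-repeat threshold above which a chromosome is labelled mutant.
MUTANT_REPEAT_THRESHOLD = 35


@dataclass(frozen=True)
class PlantedPas:
    """A SNP to plant: position, alleles and the PAS class it must realise."""

    position: int
    ref_allele: str
    alt_allele: str
    pas_class: str  # ref_generating | alt_generating | both | none


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    seed: int = 0
    # gene / reference
    gene_length: int = 6000
    n_exons: int = 8
    planted_pas: list[PlantedPas] | None = None  # None -> default design (see below)
    n_decoy_snps: int = 20  # non-PAS coding SNPs planted alongside
    # population
    n_haplotypes: int = 8
    haplotype_freqs: tuple[float, ...] = DEFAULT_HAPLOTYPE_FREQS
    n_subjects: int = 1000
    within_haplotype_noise: float = 0.05  # minor-allele rate at PAS within a haplotype
    pam_absent_haplotype: int | None = None  # index; None -> last (hap.08-like)
    on_none_pas_indices: tuple[int, ...] = (1,)
    polymorphic_pas_index: int = 0
    # amplicon editing
    per_allele_edit_fraction: tuple[float, float] = (0.1607, 0.0)  # (mutant, normal)
    indel_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_LENGTHS)
    )
    n_reads_per_allele: int = 10_000
    # allele-specific expression
    n_clones_per_group: int = 12
    n_ase_sites: int = 10
    allelic_fold_change: float = 10.0
    ase_mean_count: float = 100.0
    ase_clone_noise_sd: float = 0.1
    # gene scores / enrichment
    n_genes: int = 16_840
    enriched_set_size: int = 52
    enrichment_effect: float = 0.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.haplotype_freqs, dtype=float)
        if len(freqs) != self.n_haplotypes:
            raise GenerationError(
                f"haplotype_freqs has length {len(freqs)}, expected {self.n_haplotypes}"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise GenerationError(f"haplotype_freqs sum to {freqs.sum()}, not 1")
        if (freqs < 0).any():
            raise GenerationError("haplotype frequencies must be non-negative")
        for p in (*self.per_allele_edit_fraction, *self.indel_length_distribution.values(),
                  self.within_haplotype_noise):
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"probability {p} outside [0, 1]")
        if abs(sum(self.indel_length_distribution.values()) - 1.0) > 1e-9:
            raise GenerationError("indel_length_distribution must sum to 1")
        if self.allelic_fold_change <= 0:
            raise GenerationError("allelic_fold_change must be positive")
        if self.enriched_set_size > self.n_genes:
            raise GenerationError("enriched_set_size exceeds n_genes")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific stream: master seed crossed with the stage name."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    def haplotype_names(self) -> list[str]:
        return [f"hap.{i + 1:02d}" for i in range(self.n_haplotypes)]


# ---------------------------------------------------------------------------
# reference + exon model
# ---------------------------------------------------------------------------

# 7-mer context templates centred on the planted SNP; each guarantees the
# intended class for NGG when the surrounding sequence cannot interfere
# (verified post hoc with the scanner in all cases).
_STOPS = {"TAA", "TAG", "TGA"}


def _plant_template(p: PlantedPas) -> str:
    ref, alt, cls = p.ref_allele, p.alt_allele, p.pas_class
    if cls == "ref_generating":
        if ref != "G" or alt == "G":
            raise GenerationError(
                f"planted PAS at {p.position}: ref_generating requires ref G (got {ref}/{alt})"
            )
        return "TTA" + ref + "GTT"
    if cls == "alt_generating":
        if alt != "G" or ref == "G":
            raise GenerationError(
                f"planted PAS at {p.position}: alt_generating requires alt G (got {ref}/{alt})"
            )
        return "TTA" + ref + "GTT"
    if cls == "both":
        if {ref, alt} != {"G", "C"}:
            raise GenerationError(
                f"planted PAS at {p.position}: class 'both' requires alleles G/C (got {ref}/{alt})"
            )
        return "TAG" + ref + "CTT"
    if cls == "none":
        if not {ref, alt} <= {"A", "T"}:
            raise GenerationError(
                f"planted PAS at {p.position}: class 'none' requires A/T alleles (got {ref}/{alt})"
            )
        return "TTT" + ref + "TTT"
    raise GenerationError(f"unknown planted class {cls!r} at {p.position}")


@dataclass
class SimulatedGene:
    """Reference sequence, exon/CDS model and the planted variant design."""

    sequence: str
    transcript: TranscriptModel
    pas_variants: list[tuple[Variant, str]]  # (variant, planted class)
    decoy_variants: list[Variant]  # planted coding non-PAS SNPs
    tag_variants: list[Variant]  # haplotype tag SNPs (class none)

    @property
    def all_variants(self) -> list[Variant]:
        return [v for v, _ in self.pas_variants] + self.decoy_variants + self.tag_variants

    def polymorphic_pas(self, config: "SimConfig") -> tuple[Variant, str]:
        return self.pas_variants[config.polymorphic_pas_index]


def _exon_layout(gene_length: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    """Equal-width exons separated by equal introns across the gene."""
    n_blocks = 2 * n_exons - 1
    block = gene_length // n_blocks
    if block < 20:
        raise GenerationError("gene too short for the requested exon count")
    exons = []
    for i in range(n_exons):
        start = 2 * i * block
        exons.append((start, start + block))
    return tuple(exons)


def _default_design(transcript: TranscriptModel, n_decoys: int, n_tags: int) -> tuple[
    list[PlantedPas], list[PlantedPas], list[int]
]:
    """Spread the default plant design over valid coding positions.

    Default PAS design: three ref-generating, one alt-generating, one
    'both', echoing a scan in which most PAS are reference-generated.
    """
    positions = _candidate_positions(transcript, 5 + n_decoys + n_tags)
    classes = [
        ("G", "A", "ref_generating"),
        ("G", "T", "ref_generating"),
        ("G", "A", "ref_generating"),
        ("A", "G", "alt_generating"),
        ("G", "C", "both"),
    ]
    pas = [PlantedPas(pos, r, a, c) for pos, (r, a, c) in zip(positions[:5], classes)]
    decoys = [
        PlantedPas(pos, "A", "T", "none") for pos in positions[5 : 5 + n_decoys]
    ]
    tag_positions = positions[5 + n_decoys :]
    return pas, decoys, tag_positions


def _candidate_positions(transcript: TranscriptModel, n_needed: int, margin: int = 4,
                         spacing: int = 9) -> list[int]:
    """Evenly spaced CDS positions clear of interval edges and each other.

    Positions also stay >= 25 nt from the gene ends so a 20-nt protospacer
    plus PAM always fits on the contig for any planted PAS.
    """
    gene_lo = transcript.exons[0][0] + 25
    gene_hi = transcript.exons[-1][1] - 25
    out: list[int] = []
    for s, e in transcript.cds_intervals():
        p = max(s + margin, gene_lo)
        e = min(e, gene_hi)
        while p + margin < e:
            if not out or p - out[-1] >= spacing:
                out.append(p)
                p += spacing
            else:
                p += 1
    if len(out) < n_needed:
        raise GenerationError(
            f"CDS too small to place {n_needed} planted variants (room for {len(out)})"
        )
    # spread selections across the whole CDS rather than packing the front
    idx = np.linspace(0, len(out) - 1, n_needed).round().astype(int)
    return [out[i] for i in idx]


def simulate_reference(config: SimConfig) -> SimulatedGene:
    """Random gene with planted PAS, verified by the scanner.

    The CDS starts with ATG, is stop-free in frame before planting, and
    ends with TAA. Every planted variant's realised class is verified with
    :func:`pascrispr.pamscan.classify_pas`; a plant whose context cannot
    realise its intended class raises :class:`GenerationError` naming the
    position.
    """
    if config.gene_length < 200:
        raise GenerationError("gene_length must be >= 200")
    if config.n_exons < 2:
        raise GenerationError("n_exons must be >= 2")
    rng = config.rng("reference")
    exons = _exon_layout(config.gene_length, config.n_exons)
    cds_start = exons[0][0] + 6
    cds_end = exons[-1][1] - 6
    base_model = TranscriptModel("synth_gene", exons, cds_start, cds_end)
    # trim cds_end so the spliced CDS length is a codon multiple
    spliced_len = sum(e - s for s, e in base_model.cds_intervals())
    cds_end -= spliced_len % 3
    transcript = TranscriptModel("synth_gene", exons, cds_start, cds_end)

    seq = rng.choice(list("ACGT"), size=config.gene_length)
    # start codon, then purge in-frame stops, then terminal stop
    cds_positions = [
        pos for s, e in transcript.cds_intervals() for pos in range(s, e)
    ]
    seq[cds_positions[0]], seq[cds_positions[1]], seq[cds_positions[2]] = "A", "T", "G"
    for i in range(0, len(cds_positions) - 2, 3):
        codon = seq[cds_positions[i]] + seq[cds_positions[i + 1]] + seq[cds_positions[i + 2]]
        if codon in _STOPS:
            seq[cds_positions[i]] = "C"
    for base, pos in zip("TAA", cds_positions[-3:]):
        seq[pos] = base

    if config.planted_pas is None:
        pas_plants, decoy_plants, tag_positions = _default_design(
            transcript, config.n_decoy_snps, config.n_haplotypes
        )
    else:
        pas_plants = list(config.planted_pas)
        _, decoy_plants, tag_positions = _default_design(
            transcript, config.n_decoy_snps, config.n_haplotypes
        )
        taken = {p.position for p in pas_plants}
        decoy_plants = [d for d in decoy_plants if _clear_of(d.position, taken)]
        tag_positions = [t for t in tag_positions if _clear_of(t, taken)]

    all_plants = pas_plants + decoy_plants
    _check_plant_geometry(all_plants + [PlantedPas(t, "A", "T", "none") for t in tag_positions],
                          transcript)
    for plant in all_plants:
        template = _plant_template(plant)
        seq[plant.position - 3 : plant.position + 4] = list(template)
    for t in tag_positions:
        seq[t - 3 : t + 4] = list("TTTATTT")  # tag SNP context, ref A / alt T

    sequence = "".join(seq)
    pas_variants: list[tuple[Variant, str]] = []
    for i, plant in enumerate(pas_plants):
        v = Variant("synth_gene", plant.position, plant.ref_allele, plant.alt_allele,
                    id=f"pas_{i:03d}")
        rec = classify_pas(v, sequence, PamPattern())
        if rec.pas_class != plant.pas_class:
            raise GenerationError(
                f"planted PAS at position {plant.position} realised class "
                f"{rec.pas_class!r}, wanted {plant.pas_class!r}"
            )
        pas_variants.append((v, plant.pas_class))
    decoy_variants = []
    for i, plant in enumerate(decoy_plants):
        v = Variant("synth_gene", plant.position, plant.ref_allele, plant.alt_allele,
                    id=f"snp_{i:03d}")
        rec = classify_pas(v, sequence, PamPattern())
        if rec.pas_class != "none":
            raise GenerationError(
                f"planted decoy SNP at position {plant.position} unexpectedly "
                f"realised class {rec.pas_class!r}"
            )
        decoy_variants.append(v)
    tag_variants = [
        Variant("synth_gene", t, "A", "T", id=f"tag_{i:03d}")
        for i, t in enumerate(tag_positions)
    ]
    return SimulatedGene(sequence, transcript.with_sequence(sequence), pas_variants,
                         decoy_variants, tag_variants)


def _clear_of(pos: int, taken: set[int], spacing: int = 9) -> bool:
    return all(abs(pos - t) >= spacing for t in taken)


def _check_plant_geometry(plants: list[PlantedPas], transcript: TranscriptModel) -> None:
    positions = sorted(p.position for p in plants)
    for a, b in zip(positions, positions[1:]):
        if b - a < 7:
            raise GenerationError(f"planted variants at {a} and {b} overlap (min spacing 7)")
    for p in plants:
        if not transcript.in_cds(p.position):
            raise GenerationError(f"planted variant at {p.position} is outside the CDS")
        idx = transcript.exon_index_of(p.position)
        s, e = transcript.exons[idx]
        if p.position - 3 < s or p.position + 4 > e:
            raise GenerationError(f"planted variant at {p.position} too close to an exon edge")


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


@dataclass
class SimulatedPopulation:
    """Phased cohort with planted haplotype structure and mutant labels."""

    genotypes: PhasedGenotypes
    definitions: list[HaplotypeDefinition]
    subjects: pd.DataFrame  # subject, hapA, hapB, mutant_chrom, mutant_hap, normal_hap, repeats
    chromosome_haplotypes: pd.Series  # planted truth, per chromosome
    haplotype_pas_alleles: pd.DataFrame  # haplotype x pas_id planted allele


def _haplotype_pas_alleles(config: SimConfig, gene: SimulatedGene) -> pd.DataFrame:
    """Planted allele of each PAS on each haplotype.

    The designated polymorphic PAS carries its PAM-generating allele on
    every haplotype except the PAM-absent one (hap.08-like). PAS listed in
    ``on_none_pas_indices`` carry the non-generating allele everywhere;
    everything else carries the generating allele (class 'both' is
    PAM-positive under either allele, so it gets the reference).
    """
    absent = (config.n_haplotypes - 1 if config.pam_absent_haplotype is None
              else config.pam_absent_haplotype)
    names = config.haplotype_names()
    data = {}
    for j, (variant, cls) in enumerate(gene.pas_variants):
        if cls == "ref_generating":
            gen, non = variant.ref_allele, variant.alt_allele
        elif cls == "alt_generating":
            gen, non = variant.alt_allele, variant.ref_allele
        else:  # both alleles generate a PAM; polymorphism impossible
            gen = non = variant.ref_allele
        if j in config.on_none_pas_indices and cls != "both":
            alleles = [non] * config.n_haplotypes
        elif j == config.polymorphic_pas_index and cls != "both":
            alleles = [gen] * config.n_haplotypes
            alleles[absent] = non
        else:
            alleles = [gen] * config.n_haplotypes
        data[variant.id] = alleles
    return pd.DataFrame(data, index=pd.Index(names, name="haplotype"))


def simulate_population(config: SimConfig, gene: SimulatedGene) -> SimulatedPopulation:
    """Phased cohort: haplotype-structured chromosomes, one mutant each.

    Every chromosome draws a haplotype from ``haplotype_freqs``; tag SNPs
    deterministically encode the haplotype (so assignment round-trips
    exactly); PAS alleles follow the planted haplotype scheme with
    ``within_haplotype_noise`` minor-allele flips; decoy SNPs segregate
    independently of haplotype. One chromosome per subject is labelled
    mutant via a CAG-repeat surrogate drawn above the disease threshold.
    """
    if config.n_subjects < 1:
        raise GenerationError("n_subjects must be >= 1")
    if config.n_haplotypes < 2:
        raise GenerationError("n_haplotypes must be >= 2")
    rng = config.rng("population")
    names = config.haplotype_names()
    n_chrom = 2 * config.n_subjects
    hap_idx = rng.choice(config.n_haplotypes, size=n_chrom, p=config.haplotype_freqs)

    variants = gene.all_variants
    var_frame = pd.DataFrame(
        {
            "contig": [v.contig for v in variants],
            "pos": [v.position for v in variants],
            "ref": [v.ref_allele for v in variants],
            "alt": [v.alt_allele for v in variants],
        },
        index=pd.Index([v.id for v in variants], name="id"),
    )
    codes = np.zeros((len(variants), n_chrom), dtype=np.int8)
    hap_alleles = _haplotype_pas_alleles(config, gene)
    row = {v.id: i for i, v in enumerate(variants)}
    # PAS alleles by haplotype, with minor-allele noise
    for (variant, _cls) in gene.pas_variants:
        planted = hap_alleles[variant.id].to_numpy()
        is_alt = (planted != variant.ref_allele).astype(np.int8)
        base_codes = is_alt[hap_idx]
        if config.within_haplotype_noise > 0:
            flip = rng.random(n_chrom) < config.within_haplotype_noise
            base_codes = np.where(flip, 1 - base_codes, base_codes)
        codes[row[variant.id]] = base_codes
    # decoy SNPs: haplotype-independent, MAF 0.2
    for v in gene.decoy_variants:
        codes[row[v.id]] = (rng.random(n_chrom) < 0.2).astype(np.int8)
    # tag SNPs: chromosome of haplotype i carries alt at tag i only
    for i, v in enumerate(gene.tag_variants):
        codes[row[v.id]] = (hap_idx == i).astype(np.int8)

    samples = [f"S{i:05d}" for i in range(config.n_subjects)]
    genotypes = PhasedGenotypes(var_frame, codes, samples)

    definitions = [
        HaplotypeDefinition.from_mapping(
            names[i],
            {v.id: (v.alt_allele if j == i else v.ref_allele)
             for j, v in enumerate(gene.tag_variants)},
        )
        for i in range(config.n_haplotypes)
    ]

    mutant_is_b = rng.integers(0, 2, size=config.n_subjects).astype(bool)
    mutant_repeats = rng.integers(MUTANT_REPEAT_THRESHOLD + 1, 56, size=config.n_subjects)
    normal_repeats = rng.integers(15, MUTANT_REPEAT_THRESHOLD + 1, size=config.n_subjects)
    hapA = np.array(names, dtype=object)[hap_idx[0::2]]
    hapB = np.array(names, dtype=object)[hap_idx[1::2]]
    subjects = pd.DataFrame(
        {
            "subject": samples,
            "hapA": hapA,
            "hapB": hapB,
            "mutant_chrom": np.where(mutant_is_b, "B", "A"),
            "mutant_hap": np.where(mutant_is_b, hapB, hapA),
            "normal_hap": np.where(mutant_is_b, hapA, hapB),
            "mutant_repeat": mutant_repeats,
            "normal_repeat": normal_repeats,
        }
    )
    chrom_haps = pd.Series(
        np.array(names, dtype=object)[hap_idx],
        index=genotypes.chromosome_names,
        name="haplotype",
    )
    return SimulatedPopulation(genotypes, definitions, subjects, chrom_haps, hap_alleles)


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------


def simulate_amplicon_reads(
    config: SimConfig,
    pas_variant: Variant,
    mutant_base: str,
    cut_site: int,
) -> pd.DataFrame:
    """Classified amplicon reads with planted per-allele edit fractions.

    Each read carries its allele-identifying base at the PAS and, with the
    allele's planted edit probability, one indel drawn from
    ``indel_length_distribution`` positioned within +/-2 nt of the cut
    site (so it always intersects the default editing window). Columns:
    ``read_id, allele_truth, base_at_site, indel_start, indel_length,
    passes_qc`` (``indel_length`` 0 for unedited reads).
    """
    rng = config.rng("amplicon")
    normal_base = (pas_variant.alt_allele if mutant_base == pas_variant.ref_allele
                   else pas_variant.ref_allele)
    if mutant_base not in (pas_variant.ref_allele, pas_variant.alt_allele):
        raise GenerationError(f"mutant base {mutant_base!r} is not an allele of the PAS")
    lengths = np.array(list(config.indel_length_distribution.keys()))
    probs = np.array(list(config.indel_length_distribution.values()))
    frames = []
    for allele, base, frac in (
        ("mutant", mutant_base, config.per_allele_edit_fraction[0]),
        ("normal", normal_base, config.per_allele_edit_fraction[1]),
    ):
        n = config.n_reads_per_allele
        edited = rng.random(n) < frac
        indel_len = np.where(edited, rng.choice(lengths, size=n, p=probs), 0)
        offset = rng.integers(-2, 3, size=n)
        indel_start = np.where(edited, cut_site + offset, -1)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"{allele[0]}{i:06d}" for i in range(n)],
                    "allele_truth": allele,
                    "base_at_site": base,
                    "indel_start": indel_start,
                    "indel_length": indel_len,
                    "passes_qc": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# allele-specific expression counts
# ---------------------------------------------------------------------------


def simulate_ase_counts(config: SimConfig) -> pd.DataFrame:
    """Per-clone, per-site, per-allele RNA-seq counts (long format).

    Control clones draw both alleles' counts around a common mean
    (Poisson, with a shared lognormal clone-depth factor); treated clones'
    mutant-allele means are divided by ``allelic_fold_change`` while
    normal-allele counts keep the control distribution.
    """
    if config.n_clones_per_group < 2:
        raise GenerationError("n_clones_per_group must be >= 2")
    rng = config.rng("ase")
    rows = []
    for group in ("control", "treated"):
        for c in range(config.n_clones_per_group):
            depth = float(np.exp(rng.normal(0.0, config.ase_clone_noise_sd)))
            for s in range(config.n_ase_sites):
                for allele in ("mutant", "normal"):
                    mean = config.ase_mean_count * depth
                    if group == "treated" and allele == "mutant":
                        mean /= config.allelic_fold_change
                    rows.append(
                        {
                            "site": f"site_{s:02d}",
                            "clone": f"{group[:3]}_{c:02d}",
                            "group": group,
                            "allele": allele,
                            "count": int(rng.poisson(mean)),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene significance scores
# ---------------------------------------------------------------------------


def simulate_gene_scores(config: SimConfig) -> tuple[pd.Series, list[str]]:
    """Gene significance table (-log10 FDR-like) with a planted set.

    Background scores are -log10 of uniform draws (the null shape of an
    adjusted-p scale); the planted set's scores are shifted upward by
    ``enrichment_effect`` (0 plants no signal, matching a well-behaved
    off-target screen).
    """
    rng = config.rng("genescores")
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    scores = -np.log10(rng.uniform(size=config.n_genes))
    planted = sorted(rng.choice(config.n_genes, size=config.enriched_set_size, replace=False))
    scores[planted] += config.enrichment_effect
    table = pd.Series(scores, index=pd.Index(genes, name="gene"), name="score")
    return table, [genes[i] for i in planted]
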