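"""Discovery and classification of PAM-altering SNPs (PAS).

A PAS is a single-nucleotide variant one of whose alleles creates or
destroys an occurrence of the Cas9 protospacer-adjacent motif (PAM; NGG for
SpCas9) on either strand. Classification substitutes each allele into the
reference, enumerates PAM windows overlapping the variant under both
alleles, and diffs the two site sets at identical (strand, window)
coordinates: windows that do not overlap the variant cannot differ, so only
the overlapping ones are compared.

Classes:
    ``ref_generating`` -- the reference allele carries >=1 PAM the
        alternative allele lacks (equivalently, the alternative allele
        *eliminates* a PAM);
    ``alt_generating`` -- the mirror case;
    ``both``           -- each allele carries a PAM the other lacks
        (necessarily at different windows/strands);
    ``none``           -- the variant does not alter PAM content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._seq import matches_motif, revcomp, validate_dna, validate_motif
from .transcripts import TranscriptModel

logger = logging.getLogger(__name__)

PAS_CLASSES = ("ref_generating", "alt_generating", "both", "none")


@dataclass(frozen=True)
class PamPattern:
    """A PAM motif in IUPAC code, matched on both strands."""

    motif: str = "NGG"
    name: str = "SpCas9-NGG"

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", validate_motif(self.motif))

    def __len__(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class Variant:
    """A biallelic single-nucleotide substitution, 0-based position."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            raise ValueError(
                f"variant {self.id}: alleles must be single A/C/G/T bases "
                f"(got {self.ref_allele!r}/{self.alt_allele!r})"
            )
        if ref == alt:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)

    def swapped(self) -> "Variant":
        """The same site with ref and alt exchanged (for symmetry checks)."""
        return Variant(self.contig, self.position, self.alt_allele, self.ref_allele, self.id)


@dataclass(frozen=True, order=True)
class PamSite:
    """One PAM occurrence: a strand and a genomic window of motif length."""

    start: int
    end: int
    strand: str  # "+" or "-"
    contig: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PasRecord:
    """Classification result for one variant against one PAM pattern."""

    variant: Variant
    sites_ref_only: frozenset[PamSite]
    sites_alt_only: frozenset[PamSite]
    pas_class: str
    in_cds: bool = False
    exon_index: int | None = None

    def __post_init__(self) -> None:
        if self.pas_class not in PAS_CLASSES:
            raise ValueError(f"unknown PAS class {self.pas_class!r}")

    @property
    def is_pas(self) -> bool:
        return self.pas_class != "none"

    def sites_for_allele(self, allele: str) -> frozenset[PamSite]:
        """Allele-specific PAM sites present under ``allele`` only."""
        if allele == self.variant.ref_allele:
            return self.sites_ref_only
        if allele == self.variant.alt_allele:
            return self.sites_alt_only
        raise ValueError(f"allele {allele!r} is neither ref nor alt of {self.variant.id}")

    def generating_alleles(self) -> tuple[str, ...]:
        """Alleles under which this variant carries an exclusive PAM."""
        out = []
        if self.sites_ref_only:
            out.append(self.variant.ref_allele)
        if self.sites_alt_only:
            out.append(self.variant.alt_allele)
        return tuple(out)


@dataclass
class ScanSummary:
    """Tallies of a CDS scan, under the inclusive counting convention.

    ``n_ref_generating`` counts records of class ``ref_generating`` *or*
    ``both`` (and symmetrically for alt), so that
    ``n_ref_generating + n_alt_generating - n_both == n_total``.
    """

    n_total: int
    n_ref_generating: int
    n_alt_generating: int
    n_both: int
    n_non_pas_in_cds: int = 0
    n_outside_cds: int = 0

    def identity_holds(self) -> bool:
        return self.n_ref_generating + self.n_alt_generating - self.n_both == self.n_total


def enumerate_pam_sites(
    sequence: str,
    pattern: PamPattern | str = "NGG",
    region: tuple[int, int] | None = None,
    contig: str = "",
) -> list[PamSite]:
    """Every PAM window on either strand whose window lies inside ``region``.

    Minus-strand windows are matched against the reverse complement of the
    plus-strand window. Returned sorted by (start, strand), '+' before '-'.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    seq = validate_dna(sequence)
    lo, hi = (0, len(seq)) if region is None else region
    if lo < 0 or hi > len(seq) or lo > hi:
        raise ValueError(f"region ({lo}, {hi}) outside sequence of length {len(seq)}")
    k = len(pattern)
    sites: list[PamSite] = []
    for start in range(lo, hi - k + 1):
        window = seq[start : start + k]
        if matches_motif(window, pattern.motif):
            sites.append(PamSite(start, start + k, "+", contig))
        if matches_motif(revcomp(window), pattern.motif):
            sites.append(PamSite(start, start + k, "-", contig))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _sites_overlapping(
    seq: str, pos: int, pattern: PamPattern, contig: str
) -> frozenset[PamSite]:
    """PAM sites whose window covers position ``pos``."""
    k = len(pattern)
    lo = max(0, pos - k + 1)
    hi = min(len(seq), pos + k)
    return frozenset(
        s for s in enumerate_pam_sites(seq, pattern, (lo, hi), contig) if s.start <= pos < s.end
    )


def classify_pas(
    variant: Variant,
    sequence: str,
    pattern: PamPattern | str = "NGG",
) -> PasRecord:
    """Classify one variant by diffing PAM occurrences under each allele.

    Only windows overlapping the variant position are compared; windows
    elsewhere are allele-independent. Raises if the reference sequence base
    at the variant position disagrees with the variant's reference allele.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    seq = validate_dna(sequence)
    pos = variant.position
    if not 0 <= pos < len(seq):
        raise ValueError(f"variant {variant.id} position {pos} outside sequence")
    if seq[pos] != variant.ref_allele:
        raise ValueError(
            f"variant {variant.id}: reference base at position {pos} is "
            f"{seq[pos]!r}, not the declared ref allele {variant.ref_allele!r}"
        )
    alt_seq = seq[:pos] + variant.alt_allele + seq[pos + 1 :]
    ref_sites = _sites_overlapping(seq, pos, pattern, variant.contig)
    alt_sites = _sites_overlapping(alt_seq, pos, pattern, variant.contig)
    ref_only = ref_sites - alt_sites
    alt_only = alt_sites - ref_sites
    if ref_only and alt_only:
        pas_class = "both"
    elif ref_only:
        pas_class = "ref_generating"
    elif alt_only:
        pas_class = "alt_generating"
    else:
        pas_class = "none"
    return PasRecord(variant, ref_only, alt_only, pas_class)


def scan_cds_pas(
    variants: list[Variant],
    sequence: str,
    transcript: TranscriptModel,
    pattern: PamPattern | str = "NGG",
) -> tuple[list[PasRecord], ScanSummary]:
    """Classify variants and keep coding PAS only.

    Returns the records with ``in_cds`` true and class != none, plus a
    :class:`ScanSummary` whose inclusive tallies satisfy
    ref + alt - both == total. UTR and intronic variants are excluded, as
    are coding non-PAS variants (counted separately).
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    kept: list[PasRecord] = []
    n_non_pas_cds = 0
    n_outside = 0
    for v in variants:
        rec = classify_pas(v, sequence, pattern)
        exon_idx = transcript.cds_exon_index(v.position)
        rec.in_cds = exon_idx is not None
        rec.exon_index = exon_idx
        if not rec.in_cds:
            n_outside += 1
            continue
        if not rec.is_pas:
            n_non_pas_cds += 1
            continue
        kept.append(rec)
    n_both = sum(r.pas_class == "both" for r in kept)
    summary = ScanSummary(
        n_total=len(kept),
        n_ref_generating=sum(r.pas_class in ("ref_generating", "both") for r in kept),
        n_alt_generating=sum(r.pas_class in ("alt_generating", "both") for r in kept),
        n_both=n_both,
        n_non_pas_in_cds=n_non_pas_cds,
        n_outside_cds=n_outside,
    )
    return kept, summary
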