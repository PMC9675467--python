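"""Haplotype assignment, consensus alleles, and the haplotype x PAS PAM map.

Chromosomes of a phased cohort are grouped into named haplotypes by exact
match on tag-SNP alleles; for each (haplotype, PAS) pair the modal allele
among that haplotype's chromosomes is the consensus, and PAM presence on a
haplotype follows from whether its consensus allele is a PAM-generating
allele of the PAS. A PAS whose presence differs between haplotypes is
*polymorphic* and is the raw material for allele-specific guide design.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import PhasedGenotypes
from .pamscan import PasRecord

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named haplotype defined by required alleles at tag SNPs."""

    name: str
    tag_alleles: tuple[tuple[str, str], ...]  # (variant id, required base)

    def __post_init__(self) -> None:
        if not self.tag_alleles:
            raise ValueError(f"haplotype {self.name!r} has an empty tag set")

    @classmethod
    def from_mapping(cls, name: str, tags: dict[str, str]) -> "HaplotypeDefinition":
        return cls(name, tuple(sorted(tags.items())))

    @property
    def tags(self) -> dict[str, str]:
        return dict(self.tag_alleles)


def assign_haplotypes(
    genotypes: PhasedGenotypes,
    definitions: list[HaplotypeDefinition],
) -> pd.Series:
    """Label every chromosome with a haplotype name or ``unassigned``.

    A chromosome gets a label iff it carries *all* of exactly one
    definition's tag alleles; zero or multiple matches give ``unassigned``
    (multiple matches indicate overlapping definitions and are logged).
    """
    n_chrom = genotypes.n_chromosomes
    match_counts = np.zeros(n_chrom, dtype=int)
    labels = np.array([UNASSIGNED] * n_chrom, dtype=object)
    for definition in definitions:
        mask = np.ones(n_chrom, dtype=bool)
        for vid, base in definition.tag_alleles:
            mask &= genotypes.alleles_at(vid) == base
        labels[mask & (match_counts == 0)] = definition.name
        match_counts += mask
    labels[match_counts > 1] = UNASSIGNED
    n_un = int((labels == UNASSIGNED).sum())
    n_multi = int((match_counts > 1).sum())
    if n_un:
        logger.info(
            "assign_haplotypes: %d/%d chromosomes unassigned (%d matched >1 definition)",
            n_un, n_chrom, n_multi,
        )
    return pd.Series(labels, index=genotypes.chromosome_names, name="haplotype")


def consensus_alleles(
    assignments: pd.Series,
    genotypes: PhasedGenotypes,
    pas_ids: list[str],
) -> pd.DataFrame:
    """Modal allele of each PAS within each assigned haplotype.

    Ties are broken toward the reference allele (logged). Returns a tidy
    frame with columns ``haplotype, pas_id, allele, count, frequency``;
    frequency is the consensus allele's share among that haplotype's
    chromosomes. ``unassigned`` chromosomes are excluded.
    """
    rows = []
    hap_names = [h for h in pd.unique(assignments) if h != UNASSIGNED]
    if not hap_names:
        raise ValueError("no chromosomes assigned to any haplotype")
    labels = assignments.to_numpy()
    for vid in pas_ids:
        bases = genotypes.alleles_at(vid)
        ref = genotypes.variants.loc[vid, "ref"]
        for hap in hap_names:
            hap_bases = bases[labels == hap]
            counts = Counter(hap_bases)
            top = max(counts.values())
            modal = [b for b, c in counts.items() if c == top]
            if len(modal) > 1:
                choice = ref if ref in modal else sorted(modal)[0]
                logger.info(
                    "consensus tie at %s on %s: %s -> %s (reference tie-break)",
                    vid, hap, sorted(modal), choice,
                )
            else:
                choice = modal[0]
            rows.append(
                {
                    "haplotype": hap,
                    "pas_id": vid,
                    "allele": choice,
                    "count": counts[choice],
                    "frequency": counts[choice] / len(hap_bases),
                }
            )
    return pd.DataFrame(rows)


def build_pam_map(
    consensus: pd.DataFrame,
    pas_records: list[PasRecord],
) -> pd.DataFrame:
    """Haplotype x PAS boolean PAM-presence map from consensus alleles.

    Presence is true iff the haplotype's consensus allele is one under
    which the PAS carries an exclusive PAM site (the ref allele for
    ``ref_generating``, the alt for ``alt_generating``, either for
    ``both``). Adds a per-PAS ``polymorphic`` flag: presence varies across
    haplotypes. Rows: haplotypes; columns: PAS ids.
    """
    by_id = {r.variant.id: r for r in pas_records}
    missing = set(consensus["pas_id"]) - set(by_id)
    if missing:
        raise ValueError(f"PAS without a classification record: {sorted(missing)}")
    presence = {}
    for (hap, vid), sub in consensus.groupby(["haplotype", "pas_id"], sort=True):
        rec = by_id[vid]
        allele = sub["allele"].iloc[0]
        if allele not in (rec.variant.ref_allele, rec.variant.alt_allele):
            raise ValueError(
                f"consensus allele {allele!r} at {vid} on {hap} is neither "
                f"ref ({rec.variant.ref_allele}) nor alt ({rec.variant.alt_allele})"
            )
        presence[(hap, vid)] = bool(rec.sites_for_allele(allele))
    table = pd.Series(presence).unstack()
    table.index.name = "haplotype"
    table.columns.name = "pas_id"
    return table


def find_polymorphic_pas(pam_map: pd.DataFrame) -> dict[str, list[str]]:
    """Partition PAS ids into on_all / on_none / polymorphic.

    A PAS is ``on_all`` if every haplotype carries its PAM, ``on_none`` if
    none does, and ``polymorphic`` otherwise. The three lists partition the
    map's columns.
    """
    if pam_map.empty:
        raise ValueError("PAM map is empty")
    out: dict[str, list[str]] = {"on_all": [], "on_none": [], "polymorphic": []}
    for vid in pam_map.columns:
        col = pam_map[vid]
        if col.all():
            out["on_all"].append(vid)
        elif not col.any():
            out["on_none"].append(vid)
        else:
            out["polymorphic"].append(vid)
    return out
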