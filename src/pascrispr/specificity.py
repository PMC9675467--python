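"""Diplotype-level mutant specificity of a PAS-generated PAM.

A subject's diplotype is the *ordered* pair (mutant haplotype, normal
haplotype) -- the mutant chromosome is the one carrying the expanded CAG
repeat. For a polymorphic PAS, the therapeutically useful subjects are
those whose PAM is present on the mutant chromosome and absent on the
normal one; this module computes the four cell fractions (mutant-only,
normal-only, both, neither) either from a diplotype frequency table plus a
haplotype PAM map, or directly from per-subject phased alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .haplotypes import UNASSIGNED
from .pamscan import PasRecord

logger = logging.getLogger(__name__)

CALLS = ("mutant_only", "normal_only", "both", "neither")


@dataclass
class SpecificityReport:
    """Cohort fractions of PAM mutant-specificity for one PAS."""

    pas_id: str
    fraction_mutant_only: float
    fraction_normal_only: float
    fraction_both: float
    fraction_neither: float
    eligible_diplotypes: list[tuple[str, str]] = field(default_factory=list)
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        total = (
            self.fraction_mutant_only
            + self.fraction_normal_only
            + self.fraction_both
            + self.fraction_neither
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"specificity fractions sum to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "mutant_only": self.fraction_mutant_only,
            "normal_only": self.fraction_normal_only,
            "both": self.fraction_both,
            "neither": self.fraction_neither,
        }


def diplotype_frequencies(
    records: pd.DataFrame,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Diplotype frequency table from per-subject (mutant, normal) labels.

    ``records`` needs columns ``mutant_hap`` and ``normal_hap``. Subjects
    with either chromosome unassigned are excluded (and counted in the
    log). Returns a frame with columns
    ``mutant_hap, normal_hap, count, frequency``; frequencies are over the
    included universe when ``renormalize`` (the default), else over all
    subjects including the excluded ones.
    """
    if records.empty:
        raise ValueError("no subjects in diplotype input")
    keep = (records["mutant_hap"] != UNASSIGNED) & (records["normal_hap"] != UNASSIGNED)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("diplotype_frequencies: excluded %d subjects with unassigned chromosomes",
                    n_excluded)
    included = records.loc[keep]
    if included.empty:
        raise ValueError("no subjects with fully assigned diplotypes")
    counts = (
        included.groupby(["mutant_hap", "normal_hap"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    denom = len(included) if renormalize else len(records)
    counts["frequency"] = counts["count"] / denom
    return counts


def mutant_specificity(
    table: pd.DataFrame,
    pam_map: pd.DataFrame,
    pas_id: str,
) -> SpecificityReport:
    """Specificity fractions by summing diplotype frequencies cell-wise.

    For each diplotype (m, n), presence of the PAS's PAM on m and on n is
    read from the haplotype map; the diplotype's frequency accrues to the
    corresponding cell. Haplotypes absent from the map raise.
    """
    if pas_id not in pam_map.columns:
        raise KeyError(f"PAS {pas_id!r} not in PAM map")
    presence = pam_map[pas_id]
    haps = set(table["mutant_hap"]) | set(table["normal_hap"])
    missing = haps - set(presence.index)
    if missing:
        raise KeyError(f"haplotypes missing from PAM map: {sorted(missing)}")
    cells = dict.fromkeys(CALLS, 0.0)
    eligible = []
    for row in table.itertuples(index=False):
        on_m = bool(presence[row.mutant_hap])
        on_n = bool(presence[row.normal_hap])
        call = _call(on_m, on_n)
        cells[call] += row.frequency
        if call == "mutant_only":
            eligible.append((row.mutant_hap, row.normal_hap))
    total = sum(cells.values())
    if abs(total - 1.0) > 1e-9:
        # unrenormalized table: report fractions of the included universe
        cells = {k: v / total for k, v in cells.items()}
    return SpecificityReport(
        pas_id=pas_id,
        fraction_mutant_only=cells["mutant_only"],
        fraction_normal_only=cells["normal_only"],
        fraction_both=cells["both"],
        fraction_neither=cells["neither"],
        eligible_diplotypes=eligible,
    )


def _call(pam_on_mutant: bool, pam_on_normal: bool) -> str:
    if pam_on_mutant and not pam_on_normal:
        return "mutant_only"
    if pam_on_normal and not pam_on_mutant:
        return "normal_only"
    if pam_on_mutant and pam_on_normal:
        return "both"
    return "neither"


def subject_eligibility(
    phased: pd.DataFrame,
    pas_record: PasRecord,
) -> tuple[pd.Series, SpecificityReport]:
    """Per-subject specificity calls directly from phased PAS alleles.

    ``phased`` needs columns ``mutant_allele`` and ``normal_allele``: the
    observed base on each chromosome at the PAS. A chromosome "carries the
    PAM" iff its base is a PAM-generating allele of this PAS (homozygous
    subjects legitimately call ``both`` or ``neither``). Returns the
    per-subject call series and the cohort-fraction report.
    """
    if phased.empty:
        raise ValueError("no subjects in phased allele input")
    if phased[["mutant_allele", "normal_allele"]].isna().any().any():
        raise ValueError("missing phased allele (unphased subject?)")
    generating = set(pas_record.generating_alleles())
    calls = pd.Series(
        [
            _call(m in generating, n in generating)
            for m, n in zip(phased["mutant_allele"], phased["normal_allele"])
        ],
        index=phased.index,
        name="call",
    )
    frac = calls.value_counts(normalize=True).reindex(CALLS, fill_value=0.0)
    report = SpecificityReport(
        pas_id=pas_record.variant.id,
        fraction_mutant_only=float(frac["mutant_only"]),
        fraction_normal_only=float(frac["normal_only"]),
        fraction_both=float(frac["both"]),
        fraction_neither=float(frac["neither"]),
        n_subjects=len(phased),
    )
    return calls, report
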