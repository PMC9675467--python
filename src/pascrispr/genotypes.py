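"""In-memory container for phased biallelic genotypes.

Chromosome-major layout: each subject contributes two named chromosomes
(``<sample>.0`` and ``<sample>.1``, the two phased VCF alleles in order),
and genotypes are stored as a variants x chromosomes matrix of 0/1 allele
codes. Only phased, biallelic SNV records are representable; ingest from
VCF decomposes or drops anything else (see :mod:`pascrispr.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhasedGenotypes:
    """Phased allele codes for a cohort.

    Parameters
    ----------
    variants:
        DataFrame indexed by variant id with columns
        ``contig, pos, ref, alt`` (``pos`` 0-based).
    codes:
        int8 array of shape (n_variants, n_chromosomes) with values 0
        (reference allele) or 1 (alternative allele).
    samples:
        Sample names; chromosomes are ordered sample-major, haplotype A
        then B for each sample.
    """

    variants: pd.DataFrame
    codes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D variants x chromosomes array")
        if self.codes.shape[0] != len(self.variants):
            raise ValueError("codes row count must equal the number of variants")
        if self.codes.shape[1] != 2 * len(self.samples):
            raise ValueError("codes must have two chromosome columns per sample")
        if not np.isin(self.codes, (0, 1)).all():
            raise ValueError("allele codes must be 0 or 1 (phased biallelic)")

    # -- shape ------------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_chromosomes(self) -> int:
        return self.codes.shape[1]

    @property
    def chromosome_names(self) -> list[str]:
        return [f"{s}.{h}" for s in self.samples for h in (0, 1)]

    # -- lookups ----------------------------------------------------------

    def variant_row(self, variant_id: str) -> int:
        try:
            return int(self.variants.index.get_loc(variant_id))
        except KeyError:
            raise KeyError(f"variant id {variant_id!r} not in genotype table") from None

    def alleles_at(self, variant_id: str) -> np.ndarray:
        """Observed bases (not codes) for every chromosome at one variant."""
        i = self.variant_row(variant_id)
        rec = self.variants.iloc[i]
        bases = np.array([rec["ref"], rec["alt"]])
        return bases[self.codes[i]]

    def subject_alleles(self, variant_id: str) -> pd.DataFrame:
        """Per-sample phased bases at one variant (columns hapA, hapB)."""
        bases = self.alleles_at(variant_id)
        return pd.DataFrame(
            {"hapA": bases[0::2], "hapB": bases[1::2]}, index=pd.Index(self.samples, name="sample")
        )
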