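"""Per-allele editing efficiency from classified amplicon reads.

Reads from a deep-sequenced amplicon spanning the cut site are assumed to
be pre-classified into indel operations (alignment is out of scope); each
read is assigned to the mutant or normal allele by its base at the
discriminating PAS, and counted as edited iff an indel intersects a window
around the Cas9 cut site. Frame class follows the net signed indel length
within the window modulo 3. Substitutions are deliberately not treated as
editing, which makes the edited/unedited call robust to sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Default half-width (nt) of the editing window around the cut site.
DEFAULT_WINDOW_HALFWIDTH = 10

ALLELE_CALLS = ("mutant", "normal", "ambiguous")


@dataclass(frozen=True)
class IndelOp:
    """One indel in a read: start position and signed net length.

    ``length`` < 0 is a deletion of ``-length`` bases starting at ``start``;
    ``length`` > 0 is an insertion of ``length`` bases before ``start``.
    """

    start: int
    length: int

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic footprint: deletions span their bases, insertions are points."""
        if self.length < 0:
            return (self.start, self.start - self.length)
        return (self.start, self.start)


@dataclass
class ClassifiedRead:
    """One amplicon read after allele and indel classification."""

    read_id: str
    allele_call: str  # mutant | normal | ambiguous
    indel_ops: tuple[IndelOp, ...] = ()
    passes_qc: bool = True

    def __post_init__(self) -> None:
        if self.allele_call not in ALLELE_CALLS:
            raise ValueError(f"unknown allele call {self.allele_call!r}")


def assign_read_allele(
    base_at_site: str | None,
    mutant_base: str,
    normal_base: str,
) -> str:
    """Allele call from the read's base at the discriminating variant.

    A read whose base matches neither linked allele, or in which the site
    is deleted (``base_at_site`` None), is ``ambiguous`` and excluded from
    all denominators.
    """
    if base_at_site is None:
        return "ambiguous"
    base = base_at_site.upper()
    if base == mutant_base.upper():
        return "mutant"
    if base == normal_base.upper():
        return "normal"
    return "ambiguous"


def classify_edit(
    ops: tuple[IndelOp, ...] | list[IndelOp],
    cut_site: int,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> tuple[bool, int]:
    """(edited?, net length) for one read's indel ops at the cut window.

    A read is edited iff at least one op's interval intersects the closed
    window ``[cut_site - w, cut_site + w]``; the net length is the sum of
    the signed lengths of the intersecting ops.
    """
    lo, hi = cut_site - window_halfwidth, cut_site + window_halfwidth
    net = 0
    edited = False
    for op in ops:
        a, b = op.interval
        if op.length > 0:
            hit = lo <= a <= hi  # insertion point inside the closed window
        else:
            hit = a <= hi and b > lo  # deleted bases [a, b) overlap the window
        if hit:
            edited = True
            net += op.length
    return edited, net


@dataclass
class AlleleEditingRow:
    """Editing summary for one allele (one row of the output table)."""

    allele: str
    n_reads: int
    n_edited: int
    pct_edited: float
    pct_in_frame: float | None  # None when no edited reads
    pct_out_of_frame: float | None
    no_data: bool = False


@dataclass
class AlleleEditingSummary:
    """Per-allele editing efficiency and frame composition."""

    rows: dict[str, AlleleEditingRow]
    n_ambiguous: int
    cut_site: int
    window_halfwidth: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for allele in ("mutant", "normal"):
            r = self.rows[allele]
            recs.append(
                {
                    "allele": allele,
                    "n_reads": r.n_reads,
                    "n_edited": r.n_edited,
                    "pct_edited": r.pct_edited,
                    "pct_in_frame": r.pct_in_frame,
                    "pct_out_of_frame": r.pct_out_of_frame,
                    "no_data": r.no_data,
                }
            )
        return pd.DataFrame(recs)


def summarize_editing(
    reads: list[ClassifiedRead],
    cut_site: int,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> AlleleEditingSummary:
    """Per-allele % edited and in-/out-of-frame fractions.

    Ambiguous and QC-failing reads are excluded from every denominator.
    ``pct_edited`` is per allele; frame percentages are of that allele's
    *edited* reads and sum to 100 when any exist. An allele with zero reads
    is marked ``no_data`` rather than reported as 0 %.
    """
    usable = [r for r in reads if r.passes_qc and r.allele_call != "ambiguous"]
    if not usable:
        raise ValueError("no QC-passing, allele-assignable reads")
    rows: dict[str, AlleleEditingRow] = {}
    for allele in ("mutant", "normal"):
        sub = [r for r in usable if r.allele_call == allele]
        if not sub:
            rows[allele] = AlleleEditingRow(allele, 0, 0, 0.0, None, None, no_data=True)
            continue
        n_edited = 0
        n_in_frame = 0
        for r in sub:
            edited, net = classify_edit(r.indel_ops, cut_site, window_halfwidth)
            if edited:
                n_edited += 1
                if net % 3 == 0:
                    n_in_frame += 1
        pct_edited = 100.0 * n_edited / len(sub)
        if n_edited:
            pct_in = 100.0 * n_in_frame / n_edited
            pct_out = 100.0 - pct_in
        else:
            pct_in = pct_out = None
        rows[allele] = AlleleEditingRow(allele, len(sub), n_edited, pct_edited, pct_in, pct_out)
    n_ambiguous = sum(1 for r in reads if r.passes_qc and r.allele_call == "ambiguous")
    return AlleleEditingSummary(rows, n_ambiguous, cut_site, window_halfwidth)
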