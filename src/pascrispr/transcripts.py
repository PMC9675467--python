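"""Transcript/exon models on a genomic contig.

A :class:`TranscriptModel` is the minimal gene structure the pipeline needs:
a set of non-overlapping exon intervals on a plus-strand contig, with a CDS
delimited by genomic start/end coordinates. All coordinates are 0-based,
half-open. Minus-strand genes are handled upstream by reverse-complementing
the contig; the scanning and editing machinery itself is strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure plus CDS bounds for one transcript on one contig.

    Parameters
    ----------
    contig:
        Contig / chromosome name.
    exons:
        Strictly increasing, non-overlapping ``(start, end)`` intervals.
    cds_start, cds_end:
        Genomic bounds of the coding sequence. ``cds_start`` must fall in
        the first coding exon and ``cds_end`` in the last.
    sequence:
        Contig sequence (the full contig, not just the transcript), used
        for splicing and translation. Optional for purely positional work.
    net_indel:
        Cumulative signed length of indels applied via
        :func:`pascrispr.guides.apply_indel`; 0 for an unedited model.
    """

    contig: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str | None = None
    net_indel: int = 0

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty or inverted exon ({start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
            raise ValueError("CDS bounds must lie within the exon span")

    # -- interval helpers -------------------------------------------------

    def exon_index_of(self, pos: int) -> int | None:
        """Index of the exon containing genomic ``pos``, or None (intronic)."""
        for i, (start, end) in enumerate(self.exons):
            if start <= pos < end:
                return i
        return None

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exonic intervals clipped to the CDS bounds."""
        out = []
        for start, end in self.exons:
            s, e = max(start, self.cds_start), min(end, self.cds_end)
            if s < e:
                out.append((s, e))
        return out

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals())

    def cds_exon_index(self, pos: int) -> int | None:
        """Exon index if ``pos`` is coding, else None."""
        idx = self.exon_index_of(pos)
        if idx is None or not self.in_cds(pos):
            return None
        return idx

    # -- splicing ---------------------------------------------------------

    def spliced_sequence(self) -> str:
        """Concatenated exon sequence (the mature mRNA, 5'->3')."""
        if self.sequence is None:
            raise ValueError("transcript model has no sequence attached")
        return "".join(self.sequence[s:e] for s, e in self.exons)

    def genomic_to_spliced(self, pos: int) -> int:
        """Map an exonic genomic coordinate to a spliced coordinate."""
        offset = 0
        for start, end in self.exons:
            if start <= pos < end:
                return offset + (pos - start)
            offset += end - start
        raise ValueError(f"position {pos} is not exonic")

    def junction_positions(self) -> list[int]:
        """Spliced coordinates of each exon-exon junction (end of exon i)."""
        out, offset = [], 0
        for start, end in self.exons[:-1]:
            offset += end - start
            out.append(offset)
        return out

    def iter_exons(self) -> Iterator[tuple[int, int, int]]:
        for i, (s, e) in enumerate(self.exons):
            yield i, s, e

    def with_sequence(self, sequence: str) -> "TranscriptModel":
        return replace(self, sequence=sequence)
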