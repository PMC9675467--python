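"""Allele-specific guide design and premature-stop / NMD prediction.

Guide geometry follows standard SpCas9 conventions: a 20-nt protospacer
immediately 5' of the PAM on the PAM strand, with a blunt cut 3 nt 5' of
the PAM (between protospacer positions 17 and 18). A design is emitted only
for PAM sites that exist under one allele and not the other -- that
exclusivity is what confers allele specificity, since a missing PAM on the
untargeted chromosome prevents Cas9 engagement altogether. Targeting a SNP
through the protospacer (allele discrimination by gRNA hybridisation
mismatch) is deliberately refused: single protospacer mismatches are
tolerated by Cas9 and lose specificity.

Repair outcomes are modelled downstream of the cut as user-supplied indels;
:func:`predict_ptc_nmd` translates the edited spliced CDS to its first stop
and applies the canonical 50-55-nt rule: a termination codon ending >= 55 nt
upstream of the last exon-exon junction is predicted to trigger
nonsense-mediated decay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from ._seq import revcomp, validate_dna
from .pamscan import PamSite, PasRecord
from .transcripts import TranscriptModel

#: Distance threshold (nt) of the termination codon upstream of the last
#: exon-exon junction beyond which NMD is predicted (50-55-nt rule).
NMD_JUNCTION_THRESHOLD = 55

PROTOSPACER_LENGTH = 20
#: Blunt SpCas9 cut, this many nt 5' of the PAM on the PAM strand.
CUT_OFFSET_FROM_PAM = 3


@dataclass(frozen=True)
class GuideDesign:
    """One allele-specific guide anchored at a PAS-generated PAM."""

    pas_id: str
    strand: str
    protospacer: str  # 5'->3' in PAM-strand orientation
    pam_window: tuple[int, int]
    pam_sequence: str
    cut_site: int  # genomic coordinate; cut falls immediately 5' of this base
    target_allele: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LENGTH:
            raise ValueError("protospacer must be 20 nt")


class NotAlleleSpecificError(ValueError):
    """Raised when a requested design would not discriminate alleles."""


def design_guide(
    pas_record: PasRecord,
    sequence: str,
    target_allele: str,
) -> list[GuideDesign]:
    """One guide per PAM site exclusive to ``target_allele``.

    The contig is first rewritten with the target allele substituted at the
    PAS, so the protospacer sequence reflects the targeted chromosome. PAMs
    present under both alleles are refused (not allele-specific), as is a
    design whose protospacer would run off the contig.
    """
    seq = validate_dna(sequence)
    var = pas_record.variant
    sites = pas_record.sites_for_allele(target_allele)
    if not sites:
        other = var.alt_allele if target_allele == var.ref_allele else var.ref_allele
        if pas_record.sites_for_allele(other):
            raise NotAlleleSpecificError(
                f"{var.id}: allele {target_allele!r} carries no exclusive PAM "
                f"(the PAM-generating allele is {other!r})"
            )
        raise NotAlleleSpecificError(
            f"{var.id}: not allele-specific -- no PAM exclusive to either allele"
        )
    target_seq = seq[: var.position] + target_allele + seq[var.position + 1 :]
    designs = []
    for site in sorted(sites):
        designs.append(_design_at_site(target_seq, site, pas_record.variant.id, target_allele))
    return designs


def _design_at_site(seq: str, site: PamSite, pas_id: str, target_allele: str) -> GuideDesign:
    if site.strand == "+":
        ps_start, ps_end = site.start - PROTOSPACER_LENGTH, site.start
        if ps_start < 0:
            raise ValueError(f"{pas_id}: PAM at {site.start} too close to contig start")
        protospacer = seq[ps_start:ps_end]
        cut_site = site.start - CUT_OFFSET_FROM_PAM
        pam_seq = seq[site.start : site.end]
    else:
        ps_start, ps_end = site.end, site.end + PROTOSPACER_LENGTH
        if ps_end > len(seq):
            raise ValueError(f"{pas_id}: PAM at {site.start} too close to contig end")
        protospacer = revcomp(seq[ps_start:ps_end])
        cut_site = site.end + CUT_OFFSET_FROM_PAM
        pam_seq = revcomp(seq[site.start : site.end])
    return GuideDesign(
        pas_id=pas_id,
        strand=site.strand,
        protospacer=protospacer,
        pam_window=(site.start, site.end),
        pam_sequence=pam_seq,
        cut_site=cut_site,
        target_allele=target_allele,
    )


def apply_indel(
    transcript: TranscriptModel,
    indel: tuple[int, str | int],
) -> TranscriptModel:
    """Apply one exonic indel and return the edited transcript model.

    ``indel`` is ``(position, payload)``: a str payload inserts that
    sequence immediately before ``position``; an int payload deletes that
    many bases starting at ``position``. The deletion must stay inside one
    exon (junction-spanning lesions are out of scope). Exon coordinates,
    CDS bounds and the contig sequence are all updated; ``net_indel``
    accumulates the signed length change.
    """
    if transcript.sequence is None:
        raise ValueError("transcript model has no sequence attached")
    pos, payload = indel
    exon_idx = transcript.exon_index_of(pos)
    if exon_idx is None:
        raise ValueError(f"indel position {pos} is intronic")
    seq = transcript.sequence
    if isinstance(payload, str):
        inserted = validate_dna(payload, what="insertion")
        net = len(inserted)
        new_seq = seq[:pos] + inserted + seq[pos:]
        cut_end = pos
    else:
        del_len = int(payload)
        if del_len <= 0:
            raise ValueError("deletion length must be positive")
        exon_start, exon_end = transcript.exons[exon_idx]
        if pos + del_len > exon_end:
            raise ValueError(
                f"deletion [{pos}, {pos + del_len}) spans a splice junction "
                f"(exon ends at {exon_end}); unsupported"
            )
        net = -del_len
        new_seq = seq[:pos] + seq[pos + del_len :]
        cut_end = pos + del_len
    new_exons = []
    for i, (s, e) in enumerate(transcript.exons):
        if i < exon_idx:
            new_exons.append((s, e))
        elif i == exon_idx:
            new_exons.append((s, e + net))
        else:
            new_exons.append((s + net, e + net))
    cds_start = transcript.cds_start + (net if cut_end <= transcript.cds_start else 0)
    cds_end = transcript.cds_end + (net if cut_end <= transcript.cds_end else 0)
    return replace(
        transcript,
        exons=tuple(new_exons),
        cds_start=cds_start,
        cds_end=cds_end,
        sequence=new_seq,
        net_indel=transcript.net_indel + net,
    )


@dataclass
class PtcPrediction:
    """Location of the first stop codon and the resulting NMD call."""

    stop_codon_spliced: int | None  # spliced coordinate of the stop codon start
    stop_exon_index: int | None
    distance_to_last_junction: int | None  # nt from stop codon end to last junction
    nmd_predicted: bool
    frame_class: str  # "in_frame" | "out_of_frame"
    nonstop: bool = False
    protein: str = ""


def predict_ptc_nmd(
    transcript: TranscriptModel,
    nmd_threshold: int = NMD_JUNCTION_THRESHOLD,
) -> PtcPrediction:
    """Translate the spliced CDS to its first stop and apply the NMD rule.

    NMD is predicted iff the stop codon ends at least ``nmd_threshold`` nt
    upstream of the last exon-exon junction (so a stop in the last exon is
    never NMD-prone). A CDS reaching the transcript end without a stop is
    flagged ``nonstop`` with no NMD call.
    """
    mrna = transcript.spliced_sequence()
    cds_offset = transcript.genomic_to_spliced(transcript.cds_start)
    cds = mrna[cds_offset:]
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not begin with an ATG start codon")
    frame_class = "in_frame" if transcript.net_indel % 3 == 0 else "out_of_frame"
    protein = []
    stop_spliced: int | None = None
    for i in range(0, len(cds) - 2, 3):
        aa = str(Seq(cds[i : i + 3]).translate())
        if aa == "*":
            stop_spliced = cds_offset + i
            break
        protein.append(aa)
    if stop_spliced is None:
        return PtcPrediction(None, None, None, False, frame_class, nonstop=True,
                             protein="".join(protein))
    junctions = transcript.junction_positions()
    last_junction = junctions[-1] if junctions else None
    stop_end = stop_spliced + 3
    distance = None if last_junction is None else last_junction - stop_end
    nmd = distance is not None and distance >= nmd_threshold
    # exon housing the stop codon start, in spliced coordinates
    stop_exon = 0
    offset = 0
    for i, (s, e) in enumerate(transcript.exons):
        if offset <= stop_spliced < offset + (e - s):
            stop_exon = i
            break
        offset += e - s
    return PtcPrediction(
        stop_codon_spliced=stop_spliced,
        stop_exon_index=stop_exon,
        distance_to_last_junction=distance,
        nmd_predicted=nmd,
        frame_class=frame_class,
        protein="".join(protein),
    )
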