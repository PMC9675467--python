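"""Standard-format readers and writers.

Internally everything is 0-based half-open; VCF and the tabular outputs
are 1-based on disk, converted at the boundary. Every writer here
round-trips through the matching reader. VCF is read with pysam and
written as plain (uncompressed) VCF v4.2 with phased GT fields.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .editquant import ClassifiedRead, IndelOp, assign_read_allele
from .genotypes import PhasedGenotypes
from .haplotypes import HaplotypeDefinition
from .pamscan import PasRecord, Variant
from .transcripts import TranscriptModel

logger = logging.getLogger(__name__)


# -- FASTA ------------------------------------------------------------------


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- BED (exons + CDS) ------------------------------------------------------


def write_transcript_bed(path: str | Path, transcript: TranscriptModel,
                         name: str = "transcript") -> None:
    """BED12: one line, block structure = exons, thick region = CDS."""
    start = transcript.exons[0][0]
    end = transcript.exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in transcript.exons)
    starts = ",".join(str(s - start) for s, _ in transcript.exons)
    line = "\t".join(
        [
            transcript.contig, str(start), str(end), name, "0", "+",
            str(transcript.cds_start), str(transcript.cds_end), "0",
            str(len(transcript.exons)), sizes, starts,
        ]
    )
    Path(path).write_text(line + "\n")


def read_transcript_bed(path: str | Path) -> TranscriptModel:
    line = Path(path).read_text().strip().splitlines()[0]
    f = line.split("\t")
    contig, start = f[0], int(f[1])
    cds_start, cds_end = int(f[6]), int(f[7])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    return TranscriptModel(contig, exons, cds_start, cds_end)


# -- VCF --------------------------------------------------------------------


def write_phased_vcf(path: str | Path, genotypes: PhasedGenotypes,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Plain-text VCF v4.2 with phased GT for every sample."""
    lines = ["##fileformat=VCFv4.2", "##source=pascrispr"]
    contigs = dict.fromkeys(genotypes.variants["contig"])
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples))
    order = np.argsort(genotypes.variants["pos"].to_numpy(), kind="stable")
    for i in order:
        rec = genotypes.variants.iloc[i]
        gts = genotypes.codes[i]
        gt_str = "\t".join(f"{gts[2 * j]}|{gts[2 * j + 1]}"
                           for j in range(len(genotypes.samples)))
        lines.append(
            f"{rec['contig']}\t{rec['pos'] + 1}\t{genotypes.variants.index[i]}\t"
            f"{rec['ref']}\t{rec['alt']}\t.\tPASS\t.\tGT\t{gt_str}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Read phased biallelic SNVs; decompose multiallelics; skip indels.

    Multiallelic SNV records are decomposed into one ref/alt pair per
    alternative allele (chromosomes carrying a different alt are coded as
    reference for that pair). Indel records and unphased genotypes at kept
    sites are rejected or skipped with a logged count.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    ids, contig_l, pos_l, ref_l, alt_l, rows = [], [], [], [], [], []
    n_indel = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
            n_indel += 1
            continue
        for ai, alt in enumerate(alts, start=1):
            codes = np.zeros(2 * len(samples), dtype=np.int8)
            for j, s in enumerate(samples):
                sample = rec.samples[s]
                gt = sample["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    raise ValueError(f"missing genotype for {s} at {rec.chrom}:{rec.pos}")
                if not sample.phased:
                    raise ValueError(
                        f"unphased genotype for {s} at {rec.chrom}:{rec.pos}; "
                        "phased input is required"
                    )
                codes[2 * j] = 1 if gt[0] == ai else 0
                codes[2 * j + 1] = 1 if gt[1] == ai else 0
            rid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            if len(alts) > 1:
                rid = f"{rid}:{alt}"
            ids.append(rid)
            contig_l.append(rec.chrom)
            pos_l.append(rec.pos - 1)
            ref_l.append(rec.ref.upper())
            alt_l.append(alt.upper())
            rows.append(codes)
    if n_indel:
        logger.warning("read_phased_vcf: skipped %d non-SNV records", n_indel)
    variants = pd.DataFrame(
        {"contig": contig_l, "pos": pos_l, "ref": ref_l, "alt": alt_l},
        index=pd.Index(ids, name="id"),
    )
    codes = np.array(rows, dtype=np.int8) if rows else np.zeros((0, 2 * len(samples)), np.int8)
    return PhasedGenotypes(variants, codes, samples)


def variants_from_genotypes(genotypes: PhasedGenotypes) -> list[Variant]:
    return [
        Variant(r["contig"], int(r["pos"]), r["ref"], r["alt"], id=str(i))
        for i, r in genotypes.variants.iterrows()
    ]


# -- haplotype definitions / diplotypes -------------------------------------


def write_definitions_tsv(path: str | Path, definitions: list[HaplotypeDefinition]) -> None:
    rows = [
        {"haplotype": d.name, "variant_id": vid, "allele": base}
        for d in definitions
        for vid, base in d.tag_alleles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_definitions_tsv(path: str | Path) -> list[HaplotypeDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        HaplotypeDefinition.from_mapping(name, dict(zip(sub["variant_id"], sub["allele"])))
        for name, sub in df.groupby("haplotype", sort=True)
    ]


def write_diplotypes_tsv(path: str | Path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_diplotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    for col in ("mutant_hap", "normal_hap"):
        if col not in df.columns:
            raise ValueError(f"diplotype table missing column {col!r}")
    return df


# -- PAS table --------------------------------------------------------------


def write_pas_table(path: str | Path, records: list[PasRecord]) -> None:
    """PAS table with 1-based output coordinates and site windows."""
    rows = []
    for r in records:
        sites = sorted(r.sites_ref_only | r.sites_alt_only)
        rows.append(
            {
                "id": r.variant.id,
                "contig": r.variant.contig,
                "pos": r.variant.position + 1,
                "ref": r.variant.ref_allele,
                "alt": r.variant.alt_allele,
                "class": r.pas_class,
                "in_cds": r.in_cds,
                "exon_index": r.exon_index if r.exon_index is not None else "",
                "strands": ",".join(s.strand for s in sites),
                "windows": ",".join(f"{s.start + 1}-{s.end}" for s in sites),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pas_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


# -- consensus / PAM map ----------------------------------------------------


def write_consensus_tsv(path: str | Path, consensus: pd.DataFrame) -> None:
    consensus.to_csv(path, sep="\t", index=False)


def read_consensus_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"haplotype": str, "pas_id": str, "allele": str})


def write_pam_map_tsv(path: str | Path, pam_map: pd.DataFrame) -> None:
    pam_map.astype(int).to_csv(path, sep="\t")


def read_pam_map_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


# -- amplicon reads ---------------------------------------------------------


def write_reads_tsv(path: str | Path, reads: pd.DataFrame) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "base_at_site": str})


def reads_to_classified(
    reads: pd.DataFrame, mutant_base: str, normal_base: str
) -> list[ClassifiedRead]:
    """Turn a read table into :class:`ClassifiedRead` objects.

    Expects columns ``read_id, base_at_site, indel_start, indel_length,
    passes_qc``; ``indel_length`` 0 means no indel; a missing/NaN base at
    the discriminating site yields an ambiguous call.
    """
    out = []
    for row in reads.itertuples(index=False):
        base = None if pd.isna(row.base_at_site) else str(row.base_at_site)
        call = assign_read_allele(base, mutant_base, normal_base)
        ops = ()
        if int(row.indel_length) != 0:
            ops = (IndelOp(int(row.indel_start), int(row.indel_length)),)
        out.append(ClassifiedRead(str(row.read_id), call, ops, bool(row.passes_qc)))
    return out


# -- ASE counts and gene scores ---------------------------------------------


def write_ase_counts_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def read_ase_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"site": str, "clone": str})


def write_gene_scores_tsv(path: str | Path, table: pd.Series,
                          gene_set: list[str] | None = None) -> None:
    df = pd.DataFrame({"gene": table.index, "score": table.to_numpy()})
    if gene_set is not None:
        df["in_set"] = df["gene"].isin(set(gene_set))
    df.to_csv(path, sep="\t", index=False)


def read_gene_scores_tsv(path: str | Path) -> tuple[pd.Series, list[str] | None]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    table = pd.Series(df["score"].to_numpy(), index=pd.Index(df["gene"], name="gene"),
                      name="score")
    gene_set = df.loc[df["in_set"], "gene"].tolist() if "in_set" in df.columns else None
    return table, gene_set


# -- JSON reports -----------------------------------------------------------


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
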