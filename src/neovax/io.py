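"""File formats consumed and emitted by the pipeline.

Variants travel as a minimal VCF dialect (VAF in INFO, one file per
patient and origin), coding models as FASTA with header tokens
"transcript_id strand genomic_start", patient HLA genotypes as plain
text (one allele per line), predictor tables as IEDB-shaped TSV, and
windows as FASTA/TSV mirrors keyed the way predictor output joins back.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .stats import BinderCount, TestReport
from .variants import CodingModel, GenomicVariant
from .windows import PeptideWindow

CLASS1_LOCI = ("A", "B", "C")
CLASS2_LOCI = ("DPA1", "DPB1", "DQA1", "DQB1", "DRB1", "DRB3", "DRB4", "DRB5")


def read_vcf(path, sample_id: str, origin: str) -> list[GenomicVariant]:
    """Read SNVs from the minimal VCF dialect; VAF comes from INFO."""
    out = []
    for rec in VCF(str(path)):
        if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(f"non-SNV record at {rec.CHROM}:{rec.POS} in {path}")
        vaf = rec.INFO.get("VAF")
        if vaf is None:
            raise ValueError(f"missing VAF INFO field at {rec.CHROM}:{rec.POS} in {path}")
        out.append(
            GenomicVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                vaf=round(float(vaf), 6),  # VCF floats are single precision
                sample_id=sample_id,
                origin=origin,
            )
        )
    return out


def write_vcf(path, variants: Sequence[GenomicVariant]) -> None:
    contigs = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tVAF={v.vaf:.6f}\n")


def read_coding_models(path) -> list[CodingModel]:
    """FASTA with description tokens: transcript_id strand genomic_start."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        if len(tokens) < 3:
            raise ValueError(
                f"coding-model header {rec.description!r} lacks 'transcript_id strand genomic_start'"
            )
        out.append(
            CodingModel(
                transcript_id=tokens[0],
                cds=str(rec.seq).upper(),
                strand=tokens[1],
                genomic_start=int(tokens[2]),
            )
        )
    return out


def write_coding_models(path, models: Sequence[CodingModel]) -> None:
    # headers written by hand: the strand/start tokens must follow the id
    # without SeqIO's id-prefixed description handling
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.transcript_id} {m.strand} {m.genomic_start}\n")
            for i in range(0, len(m.cds), 60):
                fh.write(m.cds[i : i + 60] + "\n")


def read_alleles(path) -> list[str]:
    """One HLA allele per line, e.g. 'HLA-A*01:01:01'."""
    alleles = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    for a in alleles:
        if not a.startswith("HLA-") or "*" not in a:
            raise ValueError(f"malformed HLA allele {a!r} in {path}")
    return alleles


def write_alleles(path, alleles: Sequence[str]) -> None:
    Path(path).write_text("".join(a + "\n" for a in alleles))


def allele_class(allele: str) -> str:
    """'I' for HLA-A/B/C, 'II' for the DP/DQ/DR loci."""
    locus = allele.removeprefix("HLA-").split("*")[0]
    if locus in CLASS1_LOCI:
        return "I"
    if locus in CLASS2_LOCI:
        return "II"
    raise ValueError(f"unrecognized HLA locus in {allele!r}")


def split_alleles_by_class(alleles: Sequence[str]) -> tuple[list[str], list[str]]:
    c1 = [a for a in alleles if allele_class(a) == "I"]
    c2 = [a for a in alleles if allele_class(a) == "II"]
    return c1, c2


def write_contexts_tsv(path, contexts) -> None:
    pd.DataFrame(
        [
            {
                "context_id": c.context_id,
                "sample_id": c.sample_id,
                "wt_window": c.wt_window,
                "mut_window": c.mut_window,
                "mut_offset": c.mut_offset,
                "vaf": c.vaf,
            }
            for c in contexts
        ]
    ).to_csv(path, sep="\t", index=False)


def write_windows_fasta(path, windows: Iterable[PeptideWindow]) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.window_id}\n{w.seq}\n")


def windows_to_frame(windows: Iterable[PeptideWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "window_id": w.window_id,
                "parent_id": w.parent_id,
                "seq": w.seq,
                "start": w.start,
                "length": w.length,
                "mhc_class": w.mhc_class,
                "is_mutated": w.is_mutated,
            }
            for w in windows
        ]
    )


def write_prediction_table(path, df: pd.DataFrame) -> None:
    """IEDB-export-shaped TSV: allele, seq_num, start, end, length,
    peptide, and percentile_rank or score."""
    df.to_csv(path, sep="\t", index=False)


def write_counts_tsv(path, counts: Sequence[BinderCount]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "mhc_class": c.mhc_class,
                "is_mutated": c.is_mutated,
                "n_pass": c.n_pass,
                "n_total": c.n_total,
                "pct": c.pct,
            }
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


def write_test_reports(path, reports: dict[str, TestReport]) -> None:
    Path(path).write_text(
        json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2) + "\n"
    )
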