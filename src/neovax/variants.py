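"""Somatic filtering and mutation-centered peptide contexts.

Turns tumor/germline SNV calls plus coding sequences into paired
mutated/wild-type peptide windows centered on the mutated residue.
Genomic positions are 1-based (VCF convention); every within-peptide
offset is 0-based; intervals are half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: sentinel results of :func:`variant_to_protein_change`
SYNONYMOUS = "synonymous"
OUTSIDE_CDS = "outside_cds"
STOP_GAIN = "stop_gain"
STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class GenomicVariant:
    """One single-nucleotide variant with its origin and allele fraction.

    ``vaf`` is the fraction of reads supporting the alternate allele and
    feeds the variant-frequency score downstream; it plays no role in the
    somatic/germline identity comparison.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float
    sample_id: str
    origin: str  # "tumor" | "germline"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1")
        if self.origin not in ("tumor", "germline"):
            raise ValueError(f"origin must be 'tumor' or 'germline', got {self.origin!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for somatic filtering."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CodingModel:
    """A coding sequence anchored on the genome.

    ``genomic_start`` is the 1-based genomic coordinate of CDS base 1 in
    transcript orientation; on the minus strand the transcript runs toward
    decreasing genomic coordinates. Variants are matched to a model by
    CHROM label equal to ``transcript_id`` (each CDS lives on its own
    contig named after the transcript).
    """

    transcript_id: str
    cds: str
    strand: str  # "+" | "-"
    genomic_start: int

    def __post_init__(self) -> None:
        bad = set(self.cds) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in CDS of {self.transcript_id}: {sorted(bad)}")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"CDS length {len(self.cds)} of {self.transcript_id} not divisible by 3")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def genomic_span(self) -> tuple[int, int]:
        """Inclusive 1-based genomic interval covered by the CDS."""
        n = len(self.cds)
        if self.strand == "+":
            return (self.genomic_start, self.genomic_start + n - 1)
        return (self.genomic_start - n + 1, self.genomic_start)


@dataclass(frozen=True)
class PeptideContext:
    """Paired mutated/wild-type peptide window centered on one mutation."""

    context_id: str
    wt_window: str
    mut_window: str
    mut_offset: int  # 0-based within the window
    wt_aa: str
    mut_aa: str
    context_len: int  # target length (17 for the comparison arm, 15 for design)
    sample_id: str
    vaf: float
    clipped: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.wt_window) != len(self.mut_window):
            raise ValueError("wt and mut windows differ in length")
        if len(self.wt_window) > self.context_len:
            raise ValueError("window longer than context_len")
        diff = [i for i, (a, b) in enumerate(zip(self.wt_window, self.mut_window)) if a != b]
        if diff != [self.mut_offset]:
            raise ValueError(
                f"windows must differ exactly at mut_offset {self.mut_offset}, differ at {diff}"
            )
        if self.wt_window[self.mut_offset] != self.wt_aa or self.mut_window[self.mut_offset] != self.mut_aa:
            raise ValueError("wt_aa/mut_aa inconsistent with windows")

    def __len__(self) -> int:
        return len(self.mut_window)


def somatic_filter(
    tumor: Sequence[GenomicVariant], germline: Sequence[GenomicVariant]
) -> list[GenomicVariant]:
    """Keep tumor variants whose (chrom, pos, ref, alt) is absent from germline.

    Input order is preserved and inputs are not modified. Both lists must
    belong to one patient.
    """
    ids = {v.sample_id for v in tumor} | {v.sample_id for v in germline}
    if len(ids) > 1:
        raise ValueError(f"mixed sample_ids in somatic_filter: {sorted(ids)}")
    germline_keys = {v.key for v in germline}
    return [v for v in tumor if v.key not in germline_keys]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code, truncating at the
    first stop codon (the stop itself is excluded)."""
    bad = set(cds) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in CDS: {sorted(bad)}")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate(to_stop=True))


def _mapped_offset(v: GenomicVariant, m: CodingModel) -> int | None:
    lo, hi = m.genomic_span()
    if not (lo <= v.pos <= hi):
        return None
    if m.strand == "+":
        return v.pos - m.genomic_start
    return m.genomic_start - v.pos


def variant_to_protein_change(
    v: GenomicVariant, m: CodingModel
) -> tuple[int, str, str] | str:
    """Map an SNV through a coding model to its amino-acid consequence.

    Returns ``(aa_index, wt_aa, mut_aa)`` (0-based residue index) for a
    missense change, or one of the sentinels ``"synonymous"``,
    ``"outside_cds"``, ``"stop_gain"``, ``"stop_loss"``. Stop-affecting
    variants are flagged rather than silently dropped so that callers can
    report attrition.
    """
    off = _mapped_offset(v, m)
    if off is None:
        return OUTSIDE_CDS
    ref_on_cds = v.ref if m.strand == "+" else v.ref.translate(_COMPLEMENT)
    alt_on_cds = v.alt if m.strand == "+" else v.alt.translate(_COMPLEMENT)
    if m.cds[off] != ref_on_cds:
        raise ValueError(
            f"ref allele {v.ref} at {v.chrom}:{v.pos} does not match CDS base "
            f"{m.cds[off]} of {m.transcript_id} at offset {off} (annotation inconsistency)"
        )
    codon_i = off // 3
    within = off % 3
    codon = m.cds[codon_i * 3 : codon_i * 3 + 3]
    mut_codon = codon[:within] + alt_on_cds + codon[within + 1 :]
    wt_aa = str(Seq(codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    if wt_aa == mut_aa:
        return SYNONYMOUS
    if mut_aa == "*":
        return STOP_GAIN
    if wt_aa == "*":
        return STOP_LOSS
    return (codon_i, wt_aa, mut_aa)


def extract_context(
    protein_wt: str,
    protein_mut: str,
    aa_index: int,
    context_len: int,
    mut_position: int,
    *,
    context_id: str = "",
    sample_id: str = "",
    vaf: float = 0.0,
) -> PeptideContext:
    """Cut the mutation-centered window from the paired proteins.

    ``mut_position`` is the 1-based residue the mutation should occupy in
    an unclipped window (9th of 17 for the comparison arm, 8th of 15 for
    the vaccine arm). Windows hitting a protein terminus are clipped, kept
    at their true shorter length, and flagged.
    """
    if not (1 <= mut_position <= context_len):
        raise ValueError(f"mut_position {mut_position} outside [1, {context_len}]")
    if not (0 <= aa_index < len(protein_wt)):
        raise ValueError(f"aa_index {aa_index} out of range for protein of length {len(protein_wt)}")
    if len(protein_wt) != len(protein_mut):
        raise ValueError("proteins differ in length")
    start = max(0, aa_index - (mut_position - 1))
    stop = min(len(protein_wt), aa_index + (context_len - mut_position) + 1)  # half-open
    wt_win = protein_wt[start:stop]
    mut_win = protein_mut[start:stop]
    clipped = (stop - start) < context_len
    return PeptideContext(
        context_id=context_id or f"ctx_{aa_index}",
        wt_window=wt_win,
        mut_window=mut_win,
        mut_offset=aa_index - start,
        wt_aa=protein_wt[aa_index],
        mut_aa=protein_mut[aa_index],
        context_len=context_len,
        sample_id=sample_id,
        vaf=vaf,
        clipped=clipped,
    )


def contexts_from_variants(
    variants: Iterable[GenomicVariant],
    models: Sequence[CodingModel],
    context_len: int,
    mut_position: int,
) -> list[PeptideContext]:
    """Full per-patient path: locate each SNV on its coding model, call the
    protein change, and extract the mutation-centered context.

    Synonymous, non-coding and stop-affecting variants are skipped with a
    logged tally. Each SNV is treated independently (co-occurring mutations
    in one codon or window are not merged).
    """
    by_contig = {m.transcript_id: m for m in models}
    out: list[PeptideContext] = []
    skipped: dict[str, int] = {}
    for v in variants:
        m = by_contig.get(v.chrom)
        if m is None:
            skipped["no_model"] = skipped.get("no_model", 0) + 1
            continue
        change = variant_to_protein_change(v, m)
        if isinstance(change, str):
            skipped[change] = skipped.get(change, 0) + 1
            continue
        aa_index, wt_aa, mut_aa = change
        protein_wt = translate_cds(m.cds)
        if aa_index >= len(protein_wt):  # past an upstream stop; cannot window
            skipped["after_stop"] = skipped.get("after_stop", 0) + 1
            continue
        protein_mut = protein_wt[:aa_index] + mut_aa + protein_wt[aa_index + 1 :]
        ctx = extract_context(
            protein_wt,
            protein_mut,
            aa_index,
            context_len,
            mut_position,
            context_id=f"{v.sample_id}|{m.transcript_id}|{v.pos}{v.ref}>{v.alt}",
            sample_id=v.sample_id,
            vaf=v.vaf,
        )
        out.append(ctx)
    if skipped:
        logger.info("contexts_from_variants skipped variants: %s", skipped)
    return out
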