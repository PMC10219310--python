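"""Synthetic cohorts for end-to-end testing without external data.

Emulates the study conditions: a small melanoma-like cohort (six
patients by default) with two dozen somatic missense SNVs each, every
variant placed so that it yields a full-length mutation-centered
context; diploid-shaped HLA allele sets; and predictor tables whose
percentile ranks are i.i.d. Uniform(0, 100) per (window, allele) — the
natural null for a rank-transformed predictor. A controllable
mutated-vs-wild-type effect multiplies mutated Class II ranks by
(1 - delta), shrinking them toward strong predicted binding without
truncation artifacts. Score metrics are i.i.d. Uniform(0, 1).

Everything is deterministic under (spec, seed). What is NOT emulated:
mutational signatures, linkage between mutations, realistic HLA allele
frequencies, and any sequence-dependence of predictor values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as nio
from .scoring import DEFAULT_DIRECTIONS, VARIABLES, WeightConfig, score_candidates
from .variants import CodingModel, GenomicVariant
from .windows import PeptideWindow

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]
_CLASS1_LOCI = ("A", "B", "C")
_CLASS2_LOCI = ("DRB1", "DQB1", "DPB1")


@dataclass(frozen=True)
class CohortSpec:
    """Knobs of the synthetic cohort; defaults mirror the study layout
    (6 patients x 24 somatic mutations -> 144 full 17-mer contexts)."""

    n_patients: int = 6
    n_mutations_per_patient: int = 24
    context_len: int = 17
    mut_position: int = 9  # 1-based residue the mutation occupies
    alleles_per_class: int = 2
    rank_shift_delta: float = 0.0
    germline_dup_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_mutations_per_patient,
               self.context_len, self.alleles_per_class) < 1:
            raise ValueError("all counts must be positive")
        if self.rank_shift_delta < 0:
            raise ValueError("rank_shift_delta must be >= 0")
        if not (0.0 <= self.germline_dup_fraction < 1.0):
            raise ValueError("germline_dup_fraction must be in [0, 1)")
        if not (1 <= self.mut_position <= self.context_len):
            raise ValueError("mut_position must lie within the context")

    @property
    def delta_effect(self) -> float:
        return min(1.0, self.rank_shift_delta)


@dataclass
class Cohort:
    """In-memory synthetic cohort; one CDS contig per mutation."""

    spec: CohortSpec
    models: list[CodingModel]
    tumor: dict[str, list[GenomicVariant]] = field(default_factory=dict)
    germline: dict[str, list[GenomicVariant]] = field(default_factory=dict)
    alleles: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.tumor)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _missense_edit(rng: np.random.Generator, codon: str) -> tuple[int, str] | None:
    """A random (position-in-codon, new-base) giving a missense, non-stop
    change; None when the codon admits none."""
    wt_aa = str(Seq(codon).translate())
    options = []
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            aa = str(Seq(codon[:i] + b + codon[i + 1 :]).translate())
            if aa != wt_aa and aa != "*":
                options.append((i, b))
    if not options:
        return None
    return options[rng.integers(0, len(options))]


def _make_variant(
    rng: np.random.Generator, sample_id: str, transcript_id: str, spec: CohortSpec
) -> tuple[CodingModel, GenomicVariant]:
    """One CDS on its own contig plus a missense SNV placed so the full
    mutation-centered window fits inside the protein."""
    n_codons = spec.context_len + 8
    tail = spec.context_len - spec.mut_position
    while True:
        cds = _random_cds(rng, n_codons)
        aa_lo = spec.mut_position - 1
        aa_hi = n_codons - tail - 1
        aa_index = int(rng.integers(aa_lo, aa_hi + 1))
        edit = _missense_edit(rng, cds[aa_index * 3 : aa_index * 3 + 3])
        if edit is not None:
            break
    within, new_base = edit
    off = aa_index * 3 + within
    strand = "+" if rng.random() < 0.5 else "-"
    anchor = 1000
    if strand == "+":
        genomic_start = anchor
        pos = genomic_start + off
        ref, alt = cds[off], new_base
    else:
        genomic_start = anchor + len(cds)
        pos = genomic_start - off
        ref, alt = cds[off].translate(_COMPLEMENT), new_base.translate(_COMPLEMENT)
    model = CodingModel(transcript_id=transcript_id, cds=cds, strand=strand,
                        genomic_start=genomic_start)
    variant = GenomicVariant(
        chrom=transcript_id, pos=pos, ref=ref, alt=alt,
        vaf=round(float(rng.uniform(0.05, 0.95)), 6),
        sample_id=sample_id, origin="tumor",
    )
    return model, variant


def _make_alleles(rng: np.random.Generator, spec: CohortSpec) -> list[str]:
    alleles = []
    for loci, n in ((_CLASS1_LOCI, spec.alleles_per_class), (_CLASS2_LOCI, spec.alleles_per_class)):
        for i in range(n):
            locus = loci[i % len(loci)]
            g1, g2 = rng.integers(1, 70), rng.integers(1, 99)
            alleles.append(f"HLA-{locus}*{g1:02d}:{g2:02d}:01")
    return alleles


def make_cohort(spec: CohortSpec) -> Cohort:
    """Coding models, tumor and germline SNV sets, and allele lists.

    Each patient receives ``n_mutations_per_patient`` somatic variants
    plus shared tumor+germline variants sized so that the duplicated
    fraction of the tumor list equals ``germline_dup_fraction`` exactly;
    somatic filtering therefore retains precisely the somatic ones.
    """
    rng = np.random.default_rng(spec.seed)
    n_som = spec.n_mutations_per_patient
    f = spec.germline_dup_fraction
    n_shared = int(round(f / (1.0 - f) * n_som)) if f > 0 else 0
    cohort = Cohort(spec=spec, models=[])
    for p in range(spec.n_patients):
        sample = f"P{p + 1:02d}"
        tumor: list[GenomicVariant] = []
        germline: list[GenomicVariant] = []
        for j in range(n_som + n_shared):
            tid = f"{sample}_T{j + 1:04d}"
            model, v = _make_variant(rng, sample, tid, spec)
            cohort.models.append(model)
            tumor.append(v)
            if j >= n_som:  # shared: present in both origins
                germline.append(dataclasses.replace(v, origin="germline"))
        cohort.tumor[sample] = tumor
        cohort.germline[sample] = germline
        cohort.alleles[sample] = _make_alleles(rng, spec)
    return cohort


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Emit the formats the pipeline consumes plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    nio.write_coding_models(outdir / "coding_models.fasta", cohort.models)
    paths["coding_models"] = str(outdir / "coding_models.fasta")
    for sample in cohort.sample_ids:
        for origin, variants in (("tumor", cohort.tumor[sample]),
                                 ("germline", cohort.germline[sample])):
            p = outdir / f"{sample}.{origin}.vcf"
            nio.write_vcf(p, variants)
            paths[f"{sample}.{origin}"] = str(p)
        ap = outdir / f"{sample}.alleles.txt"
        nio.write_alleles(ap, cohort.alleles[sample])
        paths[f"{sample}.alleles"] = str(ap)
    manifest = {"spec": dataclasses.asdict(cohort.spec), "samples": cohort.sample_ids}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = str(outdir / "manifest.json")
    return paths


def make_prediction_tables(
    windows: Sequence[PeptideWindow],
    alleles: Sequence[str],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Simulated predictor tables for one patient's windows.

    Percentile ranks are Uniform(0, 100) per (window, allele); mutated
    Class II ranks are multiplied by (1 - delta_effect). Immunogenicity
    and TAP/proteasome cover the 9-mer windows, VaxiJen the 15-mers; all
    score metrics are Uniform(0, 1). One row per unique (peptide, allele).
    """
    c1, c2 = nio.split_alleles_by_class(alleles)
    tables: dict[str, list[dict]] = {m: [] for m in
                                     ("hla1_rank", "hla2_rank", "immunogenicity",
                                      "tap_proteasome", "vaxijen")}
    seen: set[tuple[str, str, str]] = set()

    def add(metric: str, w: PeptideWindow, allele: str, value: float) -> None:
        key = (metric, w.seq, allele)
        if key in seen:
            return
        seen.add(key)
        col = "percentile_rank" if metric.endswith("_rank") else "score"
        tables[metric].append(
            {"allele": allele, "seq_num": len(tables[metric]) + 1, "start": w.start + 1,
             "end": w.start + w.length, "length": w.length, "peptide": w.seq, col: value}
        )

    shrink = 1.0 - spec.delta_effect
    for w in windows:
        if w.mhc_class == "I":
            for a in c1:
                add("hla1_rank", w, a, float(rng.uniform(0, 100)))
        if w.mhc_class == "II":
            for a in c2:
                r = float(rng.uniform(0, 100))
                if w.is_mutated:
                    r *= shrink
                add("hla2_rank", w, a, r)
        if w.length == 9:
            add("immunogenicity", w, "", float(rng.uniform(0, 1)))
            add("tap_proteasome", w, "", float(rng.uniform(0, 1)))
        if w.length == 15:
            add("vaxijen", w, "", float(rng.uniform(0, 1)))
    return {m: pd.DataFrame(rows) for m, rows in tables.items()}


def expected_pass_rate(delta: float, threshold: float = 10.0) -> float:
    """Closed-form per-(window, allele) pass probability under the
    simulated rank model: P(U(0,100) * (1 - delta) <= t)."""
    shrink = 1.0 - min(1.0, delta)
    if shrink == 0.0:
        return 1.0
    return min(1.0, threshold / (100.0 * shrink))


def hla2_rank_tensor(
    spec: CohortSpec, n_cohorts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0,100) Class II rank draws, shape (n_cohorts, n_patients,
    n_windows, n_alleles), mutated ranks shrunk by (1 - delta)."""
    n_windows = spec.n_mutations_per_patient * (spec.context_len - 15 + 1)
    shape = (n_cohorts, spec.n_patients, n_windows, spec.alleles_per_class)
    mut = rng.uniform(0, 100, size=shape) * (1.0 - spec.delta_effect)
    wt = rng.uniform(0, 100, size=shape)
    return mut, wt


def counts_from_ranks(ranks: np.ndarray, threshold: float = 10.0) -> np.ndarray:
    """Per-patient counts of windows whose best-allele rank passes; the
    vectorized equivalent of best-allele count_passing (last axis =
    alleles, second-to-last = windows)."""
    return (ranks.min(axis=-1) <= threshold).sum(axis=-1)


def simulate_hla2_counts(
    spec: CohortSpec, n_cohorts: int, seed: int, threshold: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mutated and wild-type per-patient Class II binder counts for many
    independent cohorts, shape (n_cohorts, n_patients) each. Draws from
    exactly the rank model of :func:`make_prediction_tables`."""
    rng = np.random.default_rng(seed)
    mut, wt = hla2_rank_tensor(spec, n_cohorts, rng)
    return counts_from_ranks(mut, threshold), counts_from_ranks(wt, threshold)


def plant_optimum(
    raw_table: pd.DataFrame,
    planted: Sequence[str],
    margin: float,
    *,
    directions: Mapping[str, str] = DEFAULT_DIRECTIONS,
    weights: WeightConfig = WeightConfig(),
) -> pd.DataFrame:
    """Adjust raw variable values so every planted candidate's f exceeds
    every non-planted candidate's f by at least ``margin``.

    Planted rows are moved to the column-best value (normalizing to 1 in
    every variable, hence f = 1); non-planted rows are shrunk toward the
    column-worst value by the factor (1 - margin) in normalized space, so
    their f cannot exceed 1 - margin. If the planted set already clears
    the margin the table is returned unchanged.
    """
    if not (0.0 < margin <= 1.0):
        raise ValueError(f"margin {margin} must be in (0, 1]")
    planted = list(planted)
    unknown = set(planted) - set(raw_table.index)
    if unknown:
        raise ValueError(f"planted candidates not in table: {sorted(unknown)}")
    if len(planted) == len(raw_table):
        raise ValueError("planting every candidate leaves nothing to dominate")

    current = {sv.neoantigen: sv.f
               for sv in score_candidates(raw_table, weights=weights, directions=directions)}
    others = [n for n in raw_table.index if n not in planted]
    if min(current[n] for n in planted) >= max(current[n] for n in others) + margin:
        return raw_table.copy()

    adjusted = raw_table.copy().astype(float)
    is_planted = adjusted.index.isin(planted)
    for v in VARIABLES:
        col = adjusted[v].to_numpy(dtype=float)
        higher = directions[v] == "higher_better"
        best = col.max() if higher else col.min()
        worst = col.min() if higher else col.max()
        if best == worst:
            # constant column: nudge planted to strictly dominate
            best = worst + (1.0 if higher else -1.0)
            col = np.where(is_planted, best, col)
        else:
            u = (col - worst) / (best - worst)  # orientation-free goodness in [0,1]
            u = np.where(is_planted, 1.0, u * (1.0 - margin))
            col = worst + u * (best - worst)
        adjusted[v] = col
    return adjusted
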