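"""End-to-end orchestration of the two analysis arms.

The *compare* arm mirrors the cohort analysis: somatic filtering,
17-mer contexts with the mutation at the 9th residue, Class I (9-14)
and Class II (15) windows for mutated and wild-type sequences,
percentile-rank threshold counting, and the normality-gated t-tests.

The *design* arm builds the vaccine: 15-mer contexts with the mutation
at the 8th residue, 9-mer sub-windows for the Class I tools, the
seven-variable reduction and normalization, f(n), cardinality-k subset
selection and trio concatenation into 45-mer peptides.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as nio
from .scoring import (
    DEFAULT_DIRECTIONS,
    VARIABLES,
    PredictionIndex,
    PredictionRecord,
    ScoreVector,
    WeightConfig,
    aggregate_f,
    load_prediction_table,
    reduce_to_neoantigen,
    score_candidates,
)
from .selection import SelectionResult, VaccineDesign, assemble_peptides, select_subset
from .simulate import CohortSpec, make_prediction_tables
from .stats import (
    CLASS1_THRESHOLD,
    CLASS2_THRESHOLD,
    TestReport,
    count_passing,
    normality_check,
    paired_ttest_greater,
    summarize_pct,
    two_sample_ttest,
)
from .variants import CodingModel, GenomicVariant, contexts_from_variants, somatic_filter
from .windows import (
    CLASS1_LENGTHS,
    CLASS2_LENGTH,
    PeptideWindow,
    enumerate_9mers,
    enumerate_class2,
    enumerate_pairs,
    pair_wildtype,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of both arms; defaults are the published values."""

    compare_context_len: int = 17
    compare_mut_position: int = 9
    design_context_len: int = 15
    design_mut_position: int = 8
    class1_lengths: tuple[int, ...] = CLASS1_LENGTHS
    class2_length: int = CLASS2_LENGTH
    class1_threshold: float = CLASS1_THRESHOLD
    class2_threshold: float = CLASS2_THRESHOLD
    weights: WeightConfig = field(default_factory=WeightConfig)
    k: int = 6
    group_size: int = 3
    directions: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.class1_threshold, self.class2_threshold):
            if not (0.0 < t <= 100.0):
                raise ValueError(f"threshold {t} outside (0, 100]")
        if self.compare_mut_position > self.compare_context_len:
            raise ValueError("compare mut_position beyond context length")
        if self.design_mut_position > self.design_context_len:
            raise ValueError("design mut_position beyond context length")


@dataclass
class RunReport:
    """Stage-by-stage record counts plus the statistical/selection output."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    summaries: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    counts: list = field(default_factory=list)
    normality: dict[str, TestReport] = field(default_factory=dict)
    independent_tests: dict[str, TestReport] = field(default_factory=dict)
    tests: dict[str, TestReport] = field(default_factory=dict)
    scores: list[ScoreVector] = field(default_factory=list)
    selection: SelectionResult | None = None
    design: VaccineDesign | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    config: PipelineConfig | None = None
    version: str = __version__

    def count_groups(self) -> dict[tuple[str, bool], list]:
        """Per-patient counts keyed by (mhc_class, is_mutated) — the four
        groups of the cohort comparison."""
        groups: dict[tuple[str, bool], list] = {}
        for c in self.counts:
            groups.setdefault((c.mhc_class, c.is_mutated), []).append(c)
        return groups


def _tables_to_index(tables: Mapping[str, pd.DataFrame]) -> PredictionIndex:
    records: list[PredictionRecord] = []
    for metric, df in tables.items():
        col = "percentile_rank" if metric.endswith("_rank") else "score"
        for _, row in df.iterrows():
            allele = row["allele"]
            allele = "" if pd.isna(allele) else str(allele)
            records.append(
                PredictionRecord(seq=row["peptide"], allele=allele,
                                 metric=metric, value=float(row[col]))
            )
    return PredictionIndex(records)


def rank_records_frame(
    windows: Sequence[PeptideWindow],
    alleles: Sequence[str],
    index: PredictionIndex,
    sample_id: str,
) -> pd.DataFrame:
    """Join windows against rank predictions: one row per (window, class
    allele) with the window's provenance, ready for count_passing."""
    c1, c2 = nio.split_alleles_by_class(alleles)
    rows = []
    for w in windows:
        metric = "hla1_rank" if w.mhc_class == "I" else "hla2_rank"
        for a in c1 if w.mhc_class == "I" else c2:
            rank = index.get(w.seq, a, metric)
            if rank is None:
                raise ValueError(f"missing {metric} prediction for ({w.seq!r}, {a!r})")
            rows.append(
                {"sample_id": sample_id, "mhc_class": w.mhc_class,
                 "is_mutated": w.is_mutated, "window_id": w.window_id,
                 "allele": a, "rank": rank}
            )
    return pd.DataFrame(rows)


def run_compare(
    config: PipelineConfig,
    tumor: Mapping[str, Sequence[GenomicVariant]],
    germline: Mapping[str, Sequence[GenomicVariant]],
    models: Sequence[CodingModel],
    alleles: Mapping[str, Sequence[str]],
    predictions: Mapping[str, Mapping[str, pd.DataFrame]] | None = None,
    *,
    outdir=None,
) -> RunReport:
    """Cohort comparison of mutated vs wild-type binder counts.

    ``predictions`` maps sample -> metric -> IEDB-shaped table; when
    None, tables are simulated under the null (seeded by config.seed).
    """
    report = RunReport(config=config)
    samples = sorted(tumor)
    rng = np.random.default_rng(config.seed)
    sim_spec = CohortSpec(seed=config.seed, context_len=config.compare_context_len,
                          mut_position=config.compare_mut_position)
    all_records = []
    imm_means: dict[bool, list[float]] = {True: [], False: []}
    n_contexts = n_windows = 0
    for sample in samples:
        somatic = somatic_filter(list(tumor[sample]), list(germline.get(sample, [])))
        contexts = contexts_from_variants(
            somatic, models, config.compare_context_len, config.compare_mut_position
        )
        windows = enumerate_pairs(
            contexts, class1_lengths=config.class1_lengths, class2_length=config.class2_length
        )
        n_contexts += len(contexts)
        n_windows += len(windows)
        if predictions is None:
            tables = make_prediction_tables(windows, alleles[sample], sim_spec, rng)
        else:
            tables = predictions[sample]
        idx = _tables_to_index(tables)
        all_records.append(rank_records_frame(windows, alleles[sample], idx, sample))
        # per-patient mean Class I immunogenicity of mutated vs wild-type 9-mers
        for mutated in (True, False):
            vals = [idx.get(w.seq, "", "immunogenicity")
                    for w in windows if w.length == 9 and w.is_mutated == mutated]
            vals = [v for v in vals if v is not None]
            if vals:
                imm_means[mutated].append(float(np.mean(vals)))
    records = pd.concat(all_records, ignore_index=True)
    report.stage_counts = {
        "samples": len(samples),
        "contexts": n_contexts,
        "windows": n_windows,
        "rank_records": len(records),
    }

    counts1 = count_passing(records, "I", config.class1_threshold)
    counts2 = count_passing(records, "II", config.class2_threshold)
    report.counts = counts1 + counts2

    def group(counts, mutated):
        sub = sorted((c for c in counts if c.is_mutated == mutated), key=lambda c: c.sample_id)
        return sub, np.array([c.n_pass for c in sub], dtype=float)

    for name, counts in (("hla1", counts1), ("hla2", counts2)):
        mut_c, mut_n = group(counts, True)
        wt_c, wt_n = group(counts, False)
        if len(mut_c) >= 2:
            report.summaries[f"{name}_mut_pct"] = summarize_pct(mut_c)
            report.summaries[f"{name}_wt_pct"] = summarize_pct(wt_c)
        if len(mut_c) >= 3:
            report.normality[f"{name}_mut"] = normality_check(mut_n)
            report.normality[f"{name}_wt"] = normality_check(wt_n)
        if len(mut_c) >= 2:
            report.independent_tests[name] = two_sample_ttest(mut_n, wt_n)
            report.tests[f"{name}_paired"] = paired_ttest_greater(mut_n, wt_n)
    if len(imm_means[True]) >= 2:
        report.tests["immunogenicity_paired"] = paired_ttest_greater(
            imm_means[True], imm_means[False]
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_counts_tsv(outdir / "binder_counts.tsv", report.counts)
        nio.write_test_reports(outdir / "tests.json",
                               {**report.tests, **report.independent_tests,
                                **{f"normality_{k}": v for k, v in report.normality.items()}})
        report.outputs = {"counts": str(outdir / "binder_counts.tsv"),
                          "tests": str(outdir / "tests.json")}
    return report


def candidate_raw_table(
    contexts,
    alleles: Sequence[str],
    index: PredictionIndex,
) -> tuple[pd.DataFrame, list[str]]:
    """Raw seven-variable table over one patient's full-length 15-mer
    candidates, index = neoantigen sequence, preserving input order.
    Clipped (short) contexts and duplicate sequences are dropped."""
    c1, c2 = nio.split_alleles_by_class(alleles)
    rows: dict[str, tuple] = {}
    order: list[str] = []
    for ctx in contexts:
        if len(ctx) != 15:
            logger.info("skipping clipped context %s (length %d)", ctx.context_id, len(ctx))
            continue
        neo = enumerate_class2(ctx, 15)[0]
        if neo.seq in rows:
            continue
        raw = reduce_to_neoantigen(neo, enumerate_9mers(neo), index, c1, c2, ctx.vaf)
        rows[neo.seq] = raw
        order.append(neo.seq)
    table = pd.DataFrame([rows[s] for s in order], index=order, columns=list(VARIABLES))
    return table, order


def design_from_score_table(
    norm_table: pd.DataFrame,
    *,
    weights: WeightConfig = WeightConfig(),
    k: int = 6,
    group_size: int = 3,
) -> tuple[list[ScoreVector], SelectionResult, VaccineDesign]:
    """Score-table bypass: run selection and assembly directly from a
    table of already-normalized variables (index = neoantigen, columns =
    VARIABLES). Assembly preserves the table's row order."""
    scores = [
        ScoreVector(
            neoantigen=str(neo),
            raw=tuple(float(x) for x in norm_table.loc[neo, list(VARIABLES)]),
            norm=tuple(float(x) for x in norm_table.loc[neo, list(VARIABLES)]),
            f=aggregate_f(norm_table.loc[neo, list(VARIABLES)].to_numpy(), weights),
        )
        for neo in norm_table.index
    ]
    selection = select_subset([(s.neoantigen, s.f) for s in scores], k)
    chosen = set(selection.sequences)
    ordered = [str(n) for n in norm_table.index if str(n) in chosen]
    design = assemble_peptides(ordered, group_size)
    return scores, selection, design


def run_design(
    config: PipelineConfig,
    tumor: Sequence[GenomicVariant],
    germline: Sequence[GenomicVariant],
    models: Sequence[CodingModel],
    alleles: Sequence[str],
    predictions: Mapping[str, pd.DataFrame] | None = None,
    *,
    outdir=None,
) -> RunReport:
    """Vaccine design for one patient: 15/8 contexts, seven-variable
    scoring, f(n), top-k selection, trio assembly. Concatenation follows
    the candidates' input (genomic) order."""
    report = RunReport(config=config)
    somatic = somatic_filter(list(tumor), list(germline))
    contexts = contexts_from_variants(
        somatic, models, config.design_context_len, config.design_mut_position
    )
    if predictions is None:
        windows: list[PeptideWindow] = []
        for ctx in contexts:
            if len(ctx) != 15:
                continue
            neo = enumerate_class2(ctx, 15)[0]
            wt = pair_wildtype(neo, ctx)
            windows += [neo, wt] + enumerate_9mers(neo) + enumerate_9mers(wt)
        rng = np.random.default_rng(config.seed)
        sim_spec = CohortSpec(seed=config.seed, context_len=config.design_context_len,
                              mut_position=config.design_mut_position)
        predictions = make_prediction_tables(windows, alleles, sim_spec, rng)
    index = _tables_to_index(predictions)
    raw, order = candidate_raw_table(contexts, alleles, index)
    if len(raw) < config.k:
        raise ValueError(f"only {len(raw)} candidates for k={config.k}")
    report.scores = score_candidates(raw, weights=config.weights, directions=config.directions)
    selection = select_subset([(s.neoantigen, s.f) for s in report.scores], config.k)
    chosen = set(selection.sequences)
    design = assemble_peptides([s for s in order if s in chosen], config.group_size)
    report.selection = selection
    report.design = design
    report.stage_counts = {
        "somatic_variants": len(somatic),
        "contexts": len(contexts),
        "candidates": len(raw),
        "selected": config.k,
        "peptides": len(design.peptides),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        score_df = pd.DataFrame(
            [{"neoantigen": s.neoantigen,
              **{f"N_{v}": n for v, n in zip(VARIABLES, s.norm)}, "f": s.f}
             for s in report.scores]
        )
        score_df.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        with open(outdir / "vaccine_peptides.fasta", "w") as fh:
            for i, pep in enumerate(design.peptides, 1):
                fh.write(f">peptide_{i} {'+'.join(design.constituents[i - 1])}\n{pep}\n")
        report.outputs = {"scores": str(outdir / "scores.tsv"),
                          "peptides": str(outdir / "vaccine_peptides.fasta")}
    return report


def load_prediction_dir(path) -> dict[str, pd.DataFrame]:
    """Read <metric>.tsv tables from a directory, validating each through
    load_prediction_table."""
    path = Path(path)
    tables = {}
    for metric in ("hla1_rank", "hla2_rank", "immunogenicity", "tap_proteasome", "vaxijen"):
        f = path / f"{metric}.tsv"
        if not f.exists():
            raise ValueError(f"missing prediction table for metric {metric!r}: {f}")
        load_prediction_table(f, metric)  # validation
        tables[metric] = pd.read_csv(f, sep="\t").fillna({"allele": ""})
    return tables
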