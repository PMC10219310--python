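"""Seven-variable neoantigen scoring.

For every 15-mer neoantigen candidate n a raw 7-tuple is gathered —
Class I immunogenicity, HLA-I and HLA-II binding percentile ranks,
variant frequency, antigen probability (VaxiJen), hydrophilicity (GRAVY)
and TAP/proteasome processing — then min-max normalized across the
candidate set with a per-variable direction, and aggregated into

    f(n) = 0.2 (N_imm + N_HLAI + N_HLAII) + 0.1 (N_vf + N_ap + N_hpl + N_TAP)

so that the three binding/immunogenicity variables carry double weight.
External predictors are consumed as IEDB-style TSV tables, never re-run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .windows import PeptideWindow

#: metrics carried by prediction tables; rank metrics are percentile ranks
#: in [0, 100] (lower = stronger predicted binding), score metrics are
#: unit-free predictor outputs (higher = better).
RANK_METRICS = ("hla1_rank", "hla2_rank")
SCORE_METRICS = ("immunogenicity", "tap_proteasome", "vaxijen")
METRICS = RANK_METRICS + SCORE_METRICS

#: the seven variables in ScoreVector order
VARIABLES = ("imm", "hlaI", "hlaII", "vf", "ap", "hpl", "tap")

#: normalization direction per variable; ranks and GRAVY are lower-better
#: (low GRAVY = hydrophilic, and surface exposure is what is rewarded).
DEFAULT_DIRECTIONS: dict[str, str] = {
    "imm": "higher_better",
    "hlaI": "lower_better",
    "hlaII": "lower_better",
    "vf": "higher_better",
    "ap": "higher_better",
    "hpl": "lower_better",
    "tap": "higher_better",
}


@dataclass(frozen=True)
class PredictionRecord:
    """One row of an external predictor table."""

    seq: str
    allele: str  # empty for allele-independent metrics
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric in RANK_METRICS and not (0.0 <= self.value <= 100.0):
            raise ValueError(
                f"percentile rank {self.value} for {self.seq}/{self.allele} outside [0, 100]"
            )


@dataclass(frozen=True)
class WeightConfig:
    """Non-negative variable weights summing to 1."""

    w_imm: float = 0.2
    w_hlaI: float = 0.2
    w_hlaII: float = 0.2
    w_vf: float = 0.1
    w_ap: float = 0.1
    w_hpl: float = 0.1
    w_tap: float = 0.1

    def __post_init__(self) -> None:
        w = self.as_array()
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_imm, self.w_hlaI, self.w_hlaII, self.w_vf, self.w_ap, self.w_hpl, self.w_tap]
        )


@dataclass(frozen=True)
class ScoreVector:
    """Raw and normalized variables plus the aggregate f for one candidate."""

    neoantigen: str
    raw: tuple[float, ...]  # (imm, hlaI, hlaII, vf, ap, hpl, tap)
    norm: tuple[float, ...]
    f: float


def gravy(seq: str) -> float:
    """Grand average of hydropathy: the mean Kyte-Doolittle value over the
    peptide's residues. Negative values indicate hydrophilic peptides."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r} in {seq!r}") from None


def load_prediction_table(
    path, metric: str, *, value_column: str | None = None
) -> list[PredictionRecord]:
    """Read an IEDB-shaped TSV (columns allele, peptide, and a value column,
    ``percentile_rank`` for rank metrics / ``score`` otherwise) into typed
    records. Duplicate (peptide, allele) keys are rejected."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    value_column = value_column or ("percentile_rank" if metric in RANK_METRICS else "score")
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "peptide": str})
    for col in ("allele", "peptide", value_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    values = pd.to_numeric(df[value_column], errors="coerce")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ValueError(f"non-numeric value in column {value_column!r} at row {row} of {path}")
    df["allele"] = df["allele"].fillna("")
    dup = df.duplicated(subset=["peptide", "allele"])
    if dup.any():
        k = df.loc[dup, ["peptide", "allele"]].iloc[0]
        raise ValueError(f"duplicate key (seq={k['peptide']!r}, allele={k['allele']!r}) in {path}")
    return [
        PredictionRecord(seq=p, allele=a, metric=metric, value=float(v))
        for p, a, v in zip(df["peptide"], df["allele"], values)
    ]


class PredictionIndex:
    """Lookup of predictor values keyed on (seq, allele, metric)."""

    def __init__(self, records: Iterable[PredictionRecord]):
        self._d: dict[tuple[str, str, str], float] = {}
        for r in records:
            key = (r.seq, r.allele, r.metric)
            if key in self._d:
                raise ValueError(f"duplicate prediction record {key}")
            self._d[key] = r.value

    def get(self, seq: str, allele: str, metric: str) -> float | None:
        return self._d.get((seq, allele, metric))

    def require(self, pairs: Sequence[tuple[str, str]], metric: str) -> list[float]:
        missing = [(s, a) for s, a in pairs if (s, a, metric) not in self._d]
        if missing:
            raise ValueError(f"missing {metric} predictions for (window, allele) pairs: {missing}")
        return [self._d[(s, a, metric)] for s, a in pairs]


def reduce_to_neoantigen(
    neo: PeptideWindow,
    sub9: Sequence[PeptideWindow],
    records: PredictionIndex | Iterable[PredictionRecord],
    alleles_class1: Sequence[str],
    alleles_class2: Sequence[str],
    vaf: float,
) -> tuple[float, ...]:
    """Collapse window-level predictor values to the raw 7-tuple of one
    15-mer neoantigen.

    Rank metrics take the best (minimum) percentile rank over the relevant
    windows x the patient's alleles of the matching class: HLA-I over the
    seven 9-mers, HLA-II over the 15-mer itself. Score metrics take the
    maximum: immunogenicity and TAP/proteasome over the 9-mers, VaxiJen on
    the 15-mer. Hydrophilicity is GRAVY of the 15-mer; variant frequency
    passes through.
    """
    idx = records if isinstance(records, PredictionIndex) else PredictionIndex(records)
    nine = [w.seq for w in sub9]
    hla1 = min(idx.require([(s, a) for s in nine for a in alleles_class1], "hla1_rank"))
    hla2 = min(idx.require([(neo.seq, a) for a in alleles_class2], "hla2_rank"))
    imm = max(idx.require([(s, "") for s in nine], "immunogenicity"))
    tap = max(idx.require([(s, "") for s in nine], "tap_proteasome"))
    ap = max(idx.require([(neo.seq, "")], "vaxijen"))
    hpl = gravy(neo.seq)
    return (imm, hla1, hla2, vaf, ap, hpl, tap)


def minmax_normalize(column: Sequence[float], direction: str) -> np.ndarray:
    """Affine map of a candidate-set column onto [0, 1]; the best candidate
    maps to 1 and the worst to 0. A constant column maps to all 0.5
    (neutral rather than maximally favorable or unfavorable)."""
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("empty column")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full(x.shape, 0.5)
    n = (x - lo) / (hi - lo)
    return n if direction == "higher_better" else 1.0 - n


def aggregate_f(norm: Sequence[float], w: WeightConfig = WeightConfig()) -> float:
    """Weighted sum of the seven normalized variables; lands in [0, 1]."""
    x = np.asarray(norm, dtype=float)
    if x.shape != (7,):
        raise ValueError(f"expected 7 components, got shape {x.shape}")
    if ((x < 0) | (x > 1)).any():
        raise ValueError(f"normalized components outside [0, 1]: {x}")
    return float(np.dot(w.as_array(), x))


def score_candidates(
    raw_table: pd.DataFrame,
    *,
    weights: WeightConfig = WeightConfig(),
    directions: Mapping[str, str] = DEFAULT_DIRECTIONS,
) -> list[ScoreVector]:
    """Normalize a raw candidate table (index = neoantigen sequence,
    columns = VARIABLES) over the full candidate set of one patient run
    and compute f per candidate."""
    missing = [v for v in VARIABLES if v not in raw_table.columns]
    if missing:
        raise ValueError(f"raw table missing variable columns: {missing}")
    if raw_table[list(VARIABLES)].isna().any().any():
        bad = raw_table.index[raw_table[list(VARIABLES)].isna().any(axis=1)].tolist()
        raise ValueError(f"candidates with missing values are not imputed; exclude them first: {bad}")
    norm = {v: minmax_normalize(raw_table[v].to_numpy(), directions[v]) for v in VARIABLES}
    out = []
    for i, neo in enumerate(raw_table.index):
        nvec = tuple(float(norm[v][i]) for v in VARIABLES)
        out.append(
            ScoreVector(
                neoantigen=str(neo),
                raw=tuple(float(raw_table.iloc[i][v]) for v in VARIABLES),
                norm=nvec,
                f=aggregate_f(nvec, weights),
            )
        )
    return out
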