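"""Cardinality-k subset selection and vaccine peptide assembly.

The objective F(S) = sum of f(n) over a subset S of fixed cardinality k
is additive, so the exact maximizer is the k candidates with the highest
f — selection is top-k with deterministic lexicographic tie-breaking.
Selected neoantigens are concatenated in consecutive trios into
synthesis-ready peptides (three 15-mers -> one 45-mer); no junctional-
epitope screening is performed on the fused sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class SelectionResult:
    """The chosen subset in descending-f order and its objective F(S)."""

    selected: tuple[tuple[str, float], ...]
    objective: float
    k: int

    def __post_init__(self) -> None:
        if len(self.selected) != self.k:
            raise ValueError(f"selected {len(self.selected)} candidates, expected k={self.k}")
        seqs = [s for s, _ in self.selected]
        if len(set(seqs)) != len(seqs):
            raise ValueError("repeated neoantigen in selection")
        if abs(self.objective - sum(f for _, f in self.selected)) > 1e-9:
            raise ValueError("objective inconsistent with selected f values")

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.selected]


@dataclass(frozen=True)
class VaccineDesign:
    """Concatenated peptides, group_size constituent neoantigens each."""

    peptides: tuple[str, ...]
    group_size: int
    constituents: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for pep, parts in zip(self.peptides, self.constituents):
            if "".join(parts) != pep:
                raise ValueError("peptide does not reproduce its constituents")


def select_subset(scores: Sequence[tuple[str, float]], k: int) -> SelectionResult:
    """The cardinality-k subset maximizing the sum of f values.

    Equivalent to exhaustive maximization over all C(|N|, k) subsets
    because the objective is additive. Ties in f are broken
    lexicographically by sequence for determinism.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} candidates")
    if k < 1:
        raise ValueError("k must be >= 1")
    for seq, f in scores:
        if not (f == f and abs(f) != float("inf")):
            raise ValueError(f"non-finite f for {seq}")
    ranked = sorted(scores, key=lambda t: (-t[1], t[0]))
    chosen = tuple((s, float(f)) for s, f in ranked[:k])
    return SelectionResult(selected=chosen, objective=float(sum(f for _, f in chosen)), k=k)


def assemble_peptides(selected: Sequence[str], group_size: int = 3) -> VaccineDesign:
    """Concatenate consecutive groups of neoantigens, preserving the
    caller-supplied order, into long vaccine peptides (e.g. two 45-mers
    from six 15-mers)."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if len(selected) % group_size != 0:
        raise ValueError(
            f"{len(selected)} neoantigens not divisible into groups of {group_size}"
        )
    groups = [tuple(selected[i : i + group_size]) for i in range(0, len(selected), group_size)]
    return VaccineDesign(
        peptides=tuple("".join(g) for g in groups),
        group_size=group_size,
        constituents=tuple(groups),
    )
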