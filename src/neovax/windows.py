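"""Sliding-window peptide enumeration.

Every emitted window contains the mutated residue of its parent context:
MHC Class I windows at lengths 9-14, Class II windows at length 15, and
9-mer sub-windows of 15-mer neoantigens for HLA-I / immunogenicity tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .variants import PeptideContext

logger = logging.getLogger(__name__)

CLASS1_LENGTHS: tuple[int, ...] = (9, 10, 11, 12, 13, 14)
CLASS2_LENGTH: int = 15


@dataclass(frozen=True)
class PeptideWindow:
    """One sliding-window peptide tagged by MHC class and mutated flag."""

    seq: str
    parent_id: str
    start: int  # 0-based offset within the parent context window
    length: int
    mhc_class: str  # "I" | "II"
    is_mutated: bool

    def __post_init__(self) -> None:
        if len(self.seq) != self.length:
            raise ValueError(f"seq length {len(self.seq)} != declared length {self.length}")
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"mhc_class must be 'I' or 'II', got {self.mhc_class!r}")

    @property
    def window_id(self) -> str:
        mut = "mut" if self.is_mutated else "wt"
        return f"{self.parent_id}|{self.mhc_class}|{self.length}|{self.start}|{mut}"


def _starts(ctx_len: int, mut_offset: int, length: int) -> range:
    """Starts s with s <= mut_offset <= s+length-1 and s+length <= ctx_len."""
    lo = max(0, mut_offset - length + 1)
    hi = min(mut_offset, ctx_len - length)
    return range(lo, hi + 1)


def _windows(
    ctx: PeptideContext, lengths: Iterable[int], mhc_class: str, mutated: bool
) -> list[PeptideWindow]:
    source = ctx.mut_window if mutated else ctx.wt_window
    out = []
    for length in sorted(set(lengths)):
        for s in _starts(len(ctx), ctx.mut_offset, length):
            out.append(
                PeptideWindow(
                    seq=source[s : s + length],
                    parent_id=ctx.context_id,
                    start=s,
                    length=length,
                    mhc_class=mhc_class,
                    is_mutated=mutated,
                )
            )
    return out


def enumerate_class1(
    ctx: PeptideContext, lengths: Iterable[int] = CLASS1_LENGTHS, *, mutated: bool = True
) -> list[PeptideWindow]:
    """All Class I windows (lengths 9-14 by default) covering the mutation.

    Deterministic order: by length, then start. A clipped context shorter
    than every requested length yields an empty list with a warning.
    """
    wins = _windows(ctx, lengths, "I", mutated)
    if not wins:
        logger.warning(
            "context %s (length %d) shorter than every requested Class I length",
            ctx.context_id,
            len(ctx),
        )
    return wins


def enumerate_class2(
    ctx: PeptideContext, length: int = CLASS2_LENGTH, *, mutated: bool = True
) -> list[PeptideWindow]:
    """All Class II windows (single fixed length, default 15)."""
    wins = _windows(ctx, [length], "II", mutated)
    if not wins:
        logger.warning(
            "context %s (length %d) shorter than the Class II length %d",
            ctx.context_id,
            len(ctx),
            length,
        )
    return wins


def enumerate_9mers(neoantigen: PeptideWindow) -> list[PeptideWindow]:
    """The seven 9-mer sub-windows of a 15-mer neoantigen (starts 0..6),
    used for HLA-I and Class I immunogenicity predictions."""
    if neoantigen.length != 15:
        raise ValueError(f"expected a 15-mer neoantigen, got length {neoantigen.length}")
    return [
        PeptideWindow(
            seq=neoantigen.seq[s : s + 9],
            parent_id=neoantigen.window_id,
            start=s,
            length=9,
            mhc_class="I",
            is_mutated=neoantigen.is_mutated,
        )
        for s in range(7)
    ]


def pair_wildtype(w: PeptideWindow, ctx: PeptideContext) -> PeptideWindow:
    """The wild-type (or mutated) counterpart of a window at the same
    coordinates on the parent context's other sequence."""
    if w.parent_id != ctx.context_id:
        raise ValueError(f"window parent {w.parent_id!r} is not context {ctx.context_id!r}")
    source = ctx.wt_window if w.is_mutated else ctx.mut_window
    return PeptideWindow(
        seq=source[w.start : w.start + w.length],
        parent_id=w.parent_id,
        start=w.start,
        length=w.length,
        mhc_class=w.mhc_class,
        is_mutated=not w.is_mutated,
    )


def enumerate_pairs(
    contexts: Sequence[PeptideContext],
    *,
    class1_lengths: Iterable[int] = CLASS1_LENGTHS,
    class2_length: int = CLASS2_LENGTH,
) -> list[PeptideWindow]:
    """Mutated and wild-type windows of both classes for a set of contexts,
    in deterministic order (parent, class, length, start, mutated-first)."""
    out: list[PeptideWindow] = []
    for ctx in contexts:
        for mut_w in enumerate_class1(ctx, class1_lengths) + enumerate_class2(ctx, class2_length):
            out.append(mut_w)
            out.append(pair_wildtype(mut_w, ctx))
    return out
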