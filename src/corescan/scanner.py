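"""Slide scoring matrices over sequences and report TSS-relative hits.

Coordinates follow the biology convention used for promoter maps: the TSS
base is +1, the base immediately upstream is -1, and there is no position 0.
``tss_relative`` / ``tss_absolute`` convert between this axis and 1-based
absolute columns within a record.

Hits are reported on both strands if requested. An antisense hit is scored
against the reverse complement and reported at the plus-strand coordinate of
its 5'-most base (in the motif's own reading direction), with strand "-".
All windows meeting the element cutoff are reported — downstream positional
QC consumes the full hit set, not a best-per-sequence reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .motif_model import ALPHABET, MotifModelError, ScoringMatrix

__all__ = [
    "SequenceRecord",
    "MotifHit",
    "scan",
    "tss_relative",
    "tss_absolute",
    "reverse_complement",
]

_VALID = set("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

#: integer encoding: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _nt in enumerate(ALPHABET + "N"):
    _ENCODE[ord(_nt)] = _i
#: complement in integer space (N maps to itself)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An input sequence with the 1-based column of its TSS base.

    For fixed-width promoter windows of +/-100 bp around the TSS the
    ``tss_index`` is 101.
    """

    id: str
    sequence: str
    tss_index: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise MotifModelError(
                f"record {self.id!r}: invalid characters {sorted(bad)} (allowed: A C G T N)"
            )
        if not 1 <= self.tss_index <= len(seq):
            raise MotifModelError(
                f"record {self.id!r}: tss_index {self.tss_index} outside 1..{len(seq)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One threshold-passing match of an element in a record.

    ``start_tss_rel`` is the TSS-relative position of the hit's 5'-most base
    in the motif's reading direction (for "-" strand hits that is the highest
    plus-strand coordinate of the match); ``anchor_tss_rel`` locates the
    element's anchor base on the same axis. ``length`` is the motif length,
    kept so absolute intervals can be reconstructed for BED export.
    """

    seq_id: str
    element: str
    strand: str
    start_tss_rel: int
    anchor_tss_rel: int
    score: float
    length: int


def tss_relative(position: int, tss_index: int) -> int:
    """Map a 1-based column to the zero-free TSS axis (+1 = the TSS base)."""
    d = position - tss_index
    return d + 1 if d >= 0 else d


def tss_absolute(rel: int, tss_index: int) -> int:
    """Inverse of :func:`tss_relative`."""
    if rel == 0:
        raise MotifModelError("TSS-relative coordinates have no position 0")
    return tss_index + (rel - 1 if rel > 0 else rel)


def _window_scores(enc: np.ndarray, sm: ScoringMatrix) -> np.ndarray:
    """Score every window of ``sm.length`` in an encoded sequence (N = column min)."""
    L = sm.length
    table = np.vstack([sm.scores, sm.column_min])  # row 4 handles N
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    return table[windows, np.arange(L)].sum(axis=1)


def scan(
    records: Iterable[SequenceRecord],
    matrices: Sequence[ScoringMatrix],
    strands: str = "both",
) -> list[MotifHit]:
    """Report every window scoring at or above its element's cutoff.

    Parameters
    ----------
    records
        Sequences with TSS columns attached.
    matrices
        Scoring matrices, typically from one background model shared across
        the run.
    strands
        ``"sense"`` scans the plus strand only; ``"both"`` also scans the
        reverse complement.

    Records shorter than a motif are skipped for that motif with a warning.
    Output is ordered by (sequence id, position, element, strand).
    """
    if strands not in ("sense", "both"):
        raise MotifModelError(f"strands must be 'sense' or 'both', got {strands!r}")
    matrices = list(matrices)
    if not matrices:
        raise MotifModelError("at least one scoring matrix is required")
    hits: list[MotifHit] = []
    for rec in records:
        enc = _ENCODE[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        n = len(rec)
        rc_enc = _COMPLEMENT[enc[::-1]] if strands == "both" else None
        for sm in matrices:
            L = sm.length
            if n < L:
                warnings.warn(
                    f"record {rec.id!r} ({n} bp) shorter than motif "
                    f"{sm.name!r} ({L} bp); skipped",
                    stacklevel=2,
                )
                continue
            plus = _window_scores(enc, sm)
            for k in np.nonzero(plus >= sm.cutoff)[0]:
                start_abs = int(k) + 1
                hits.append(
                    MotifHit(
                        seq_id=rec.id,
                        element=sm.name,
                        strand="+",
                        start_tss_rel=tss_relative(start_abs, rec.tss_index),
                        anchor_tss_rel=tss_relative(start_abs + sm.anchor_offset, rec.tss_index),
                        score=float(plus[k]),
                        length=L,
                    )
                )
            if rc_enc is not None:
                minus = _window_scores(rc_enc, sm)
                for k in np.nonzero(minus >= sm.cutoff)[0]:
                    # offset k in the reverse complement: the motif's 5'-most
                    # base sits at plus-strand column n - k
                    start_abs = n - int(k)
                    hits.append(
                        MotifHit(
                            seq_id=rec.id,
                            element=sm.name,
                            strand="-",
                            start_tss_rel=tss_relative(start_abs, rec.tss_index),
                            anchor_tss_rel=tss_relative(start_abs - sm.anchor_offset, rec.tss_index),
                            score=float(minus[k]),
                            length=L,
                        )
                    )
    hits.sort(key=lambda h: (h.seq_id, h.start_tss_rel, h.element, h.strand))
    return hits
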