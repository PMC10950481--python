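"""Position weight matrices, GC-aware backgrounds and log2-likelihood scoring.

A core promoter element is modelled as a position weight matrix (PWM): a
4 x L table of nucleotide probabilities ``P(i, j)`` with rows A, C, G, T.
Before scanning, a PWM is converted into a log-odds scoring matrix against a
background model derived from a single GC fraction: the background
probability of G and of C is ``gc / 2`` and of A and of T is ``(1 - gc) / 2``,
so that

    score(i, j) = log2(P(i, j) / background(i))        [bits]

A window of sequence scores as the sum of the per-position cells; windows
scoring at or above the element's cutoff are reported as hits.

Each PWM carries an ``anchor_offset`` — the 0-based offset of its
biologically functional base (for an initiator, the A+1 base at the TSS) —
which downstream modules use for TSS-relative reporting and for measuring
initiator-to-downstream-element spacing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ALPHABET",
    "NT_INDEX",
    "MotifModelError",
    "BackgroundModel",
    "Pwm",
    "ScoringMatrix",
    "background_from_gc",
    "to_scoring_matrix",
    "score_window",
    "motif_score_quantile",
    "score_distribution",
    "equal_error_cutoff",
    "pwm_from_consensus",
    "read_pwm",
    "write_pwm",
]

ALPHABET = "ACGT"
NT_INDEX: Mapping[str, int] = {nt: i for i, nt in enumerate(ALPHABET)}

#: Per-position probability profiles used when building a PWM from an IUPAC
#: consensus string: the favoured base(s) absorb most of the mass, the rest
#: is spread over the disfavoured bases.
IUPAC_PROFILES: Mapping[str, tuple[float, float, float, float]] = {
    "A": (0.85, 0.05, 0.05, 0.05),
    "C": (0.05, 0.85, 0.05, 0.05),
    "G": (0.05, 0.05, 0.85, 0.05),
    "T": (0.05, 0.05, 0.05, 0.85),
    "R": (0.45, 0.05, 0.45, 0.05),
    "Y": (0.05, 0.45, 0.05, 0.45),
    "S": (0.05, 0.45, 0.45, 0.05),
    "W": (0.45, 0.05, 0.05, 0.45),
    "K": (0.05, 0.05, 0.45, 0.45),
    "M": (0.45, 0.45, 0.05, 0.05),
    "B": (0.10, 0.30, 0.30, 0.30),
    "D": (0.30, 0.10, 0.30, 0.30),
    "H": (0.30, 0.30, 0.10, 0.30),
    "V": (0.30, 0.30, 0.30, 0.10),
    "N": (0.25, 0.25, 0.25, 0.25),
}

_COLUMN_SUM_TOL = 1e-6


class MotifModelError(ValueError):
    """Invalid PWM, background model, or scoring request."""


@dataclass(frozen=True)
class BackgroundModel:
    """Single-nucleotide background derived from a GC fraction.

    ``p[G] = p[C] = gc / 2`` and ``p[A] = p[T] = (1 - gc) / 2``; the four
    probabilities sum to 1 by construction.
    """

    gc: float
    p: Mapping[str, float]

    @property
    def vector(self) -> np.ndarray:
        """Background probabilities in A, C, G, T row order."""
        return np.array([self.p[nt] for nt in ALPHABET], dtype=float)


def background_from_gc(gc: float) -> BackgroundModel:
    """Build the background model for a GC fraction in the open interval (0, 1).

    Exactly 0 or 1 is rejected: a zero background probability makes the
    log2-likelihood undefined.
    """
    gc = float(gc)
    if not (0.0 < gc < 1.0) or math.isnan(gc):
        raise MotifModelError(
            f"GC fraction must be strictly between 0 and 1, got {gc!r}; "
            "set it explicitly if the input sequence composition is degenerate"
        )
    half_gc = gc / 2.0
    half_at = (1.0 - gc) / 2.0
    return BackgroundModel(gc=gc, p={"A": half_at, "C": half_gc, "G": half_gc, "T": half_at})


@dataclass(frozen=True)
class Pwm:
    """A named probability matrix with an anchor base and a reporting cutoff.

    Parameters
    ----------
    name
        Element identifier; must not contain whitespace (it is written as a
        ``key=value`` token in the PWM file header).
    probs
        4 x L matrix of probabilities, rows in A, C, G, T order; every column
        must sum to 1 within 1e-6.
    anchor_offset
        0-based offset within the motif of its functional base (e.g. the A+1
        of an initiator). Defaults to the first position.
    cutoff
        Minimal reportable log2 score, in bits.
    """

    name: str
    probs: np.ndarray
    anchor_offset: int = 0
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        probs = np.array(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise MotifModelError(f"PWM {self.name!r}: probs must be a 4 x L matrix")
        if np.any(probs < 0):
            raise MotifModelError(f"PWM {self.name!r}: negative probabilities")
        sums = probs.sum(axis=0)
        bad = np.where(np.abs(sums - 1.0) > _COLUMN_SUM_TOL)[0]
        if bad.size:
            raise MotifModelError(
                f"PWM {self.name!r}: column {bad[0] + 1} sums to {sums[bad[0]]:.6f}, not 1"
            )
        if not 0 <= int(self.anchor_offset) < probs.shape[1]:
            raise MotifModelError(
                f"PWM {self.name!r}: anchor_offset {self.anchor_offset} outside 0..{probs.shape[1] - 1}"
            )
        if any(ch.isspace() for ch in self.name):
            raise MotifModelError(f"PWM name {self.name!r} must not contain whitespace")
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "anchor_offset", int(self.anchor_offset))
        object.__setattr__(self, "cutoff", float(self.cutoff))

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-probability base per column (first of A,C,G,T on ties)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))


@dataclass(frozen=True)
class ScoringMatrix:
    """Log2-likelihood scores of a PWM against a fixed background.

    ``max_score`` is the sum over columns of the column maxima — the score of
    the consensus window — and is the natural reference point for cutoffs.
    """

    name: str
    scores: np.ndarray
    max_score: float
    anchor_offset: int
    cutoff: float

    def __post_init__(self) -> None:
        scores = np.array(self.scores, dtype=float)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    @property
    def column_min(self) -> np.ndarray:
        return self.scores.min(axis=0)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.scores, axis=0))


def to_scoring_matrix(
    pwm: Pwm, bg: BackgroundModel, pseudocount: float = 1e-3
) -> ScoringMatrix:
    """Convert a probability matrix to log2-likelihood scores in bits.

    Probabilities are regularized by an additive pseudocount renormalized per
    column, ``q = (P + c) / (1 + 4c)``, so that zero cells stay finite; with
    ``pseudocount=0`` a zero probability raises.
    """
    if pseudocount < 0:
        raise MotifModelError("pseudocount must be >= 0")
    q = (pwm.probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    if np.any(q <= 0):
        raise MotifModelError(
            f"PWM {pwm.name!r} has zero probabilities and pseudocount 0: "
            "log2 scores would be degenerate"
        )
    scores = np.log2(q / bg.vector[:, None])
    max_score = float(scores.max(axis=0).sum())
    if max_score < pwm.cutoff:
        warnings.warn(
            f"element {pwm.name!r}: max score {max_score:.3f} below cutoff "
            f"{pwm.cutoff:.3f} at GC {bg.gc:.3f}; it can never be reported",
            stacklevel=2,
        )
    return ScoringMatrix(
        name=pwm.name,
        scores=scores,
        max_score=max_score,
        anchor_offset=pwm.anchor_offset,
        cutoff=pwm.cutoff,
    )


def score_window(sm: ScoringMatrix, window: str) -> float:
    """Score one window of length L; ``N`` contributes the column minimum.

    Ambiguous bases are scored conservatively (they can only suppress a hit,
    never create one). Characters outside A, C, G, T, N are rejected.
    """
    window = window.upper()
    if len(window) != sm.length:
        raise MotifModelError(
            f"window length {len(window)} does not match matrix length {sm.length}"
        )
    col_min = sm.column_min
    total = 0.0
    for j, ch in enumerate(window):
        if ch == "N":
            total += col_min[j]
        else:
            try:
                total += sm.scores[NT_INDEX[ch], j]
            except KeyError:
                raise MotifModelError(f"invalid character {ch!r} in window") from None
    return float(total)


def score_distribution(
    pwm: Pwm,
    bg: BackgroundModel,
    under: str = "motif",
    pseudocount: float = 1e-3,
    bin_width: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact score distribution of a window drawn from the motif or background.

    Positions are independent, so the distribution is the convolution of the
    per-column distributions (4 support points each, weighted by the column
    probabilities under the chosen model). Returned as sorted score values on
    a discrete grid of ``bin_width`` bits plus their probabilities.
    """
    if under not in ("motif", "background"):
        raise MotifModelError("under must be 'motif' or 'background'")
    sm = to_scoring_matrix(pwm, bg, pseudocount=pseudocount)
    dist: dict[int, float] = {0: 1.0}
    for j in range(pwm.length):
        nxt: dict[int, float] = {}
        for i in range(4):
            p = pwm.probs[i, j] if under == "motif" else bg.vector[i]
            if p <= 0:
                continue
            b = round(sm.scores[i, j] / bin_width)
            for k, w in dist.items():
                nxt[k + b] = nxt.get(k + b, 0.0) + w * p
        dist = nxt
    keys = np.array(sorted(dist))
    return keys * bin_width, np.array([dist[k] for k in keys])


def motif_score_quantile(
    pwm: Pwm,
    bg: BackgroundModel,
    q: float,
    pseudocount: float = 1e-3,
    bin_width: float = 1e-3,
) -> float:
    """Lower q-quantile of the score of a sequence drawn from the PWM itself."""
    if not 0.0 < q < 1.0:
        raise MotifModelError("quantile must be in (0, 1)")
    values, probs = score_distribution(pwm, bg, "motif", pseudocount, bin_width)
    return float(values[np.searchsorted(np.cumsum(probs), q)])


def equal_error_cutoff(
    pwm: Pwm,
    bg: BackgroundModel,
    pseudocount: float = 1e-3,
    bin_width: float = 1e-3,
) -> float:
    """Cutoff where the miss rate on motif draws equals the background
    false-positive rate per window.

    The balanced (equal-error) operating point of the likelihood-ratio
    detector: scanning with this cutoff misses a fraction alpha of true
    motif instances and reports the same fraction alpha of random background
    windows. Used for the library's default cutoffs.
    """
    mv, mp = score_distribution(pwm, bg, "motif", pseudocount, bin_width)
    bv, bp = score_distribution(pwm, bg, "background", pseudocount, bin_width)
    grid = np.unique(np.concatenate([mv, bv]))
    mcum = np.cumsum(mp)
    bcum = np.cumsum(bp)
    # miss(c) = P_motif(S < c); fp(c) = P_bg(S >= c) = 1 - P_bg(S < c)
    miss = np.where(
        (i := np.searchsorted(mv, grid, side="left")) > 0, mcum[np.maximum(i - 1, 0)], 0.0
    )
    j = np.searchsorted(bv, grid, side="left")
    fp = 1.0 - np.where(j > 0, bcum[np.maximum(j - 1, 0)], 0.0)
    idx = int(np.argmin(np.abs(miss - fp)))
    return float(grid[idx])


def pwm_from_consensus(
    name: str,
    consensus: str,
    anchor_offset: int = 0,
    cutoff: float = 0.0,
    profiles: Mapping[str, Iterable[float]] = IUPAC_PROFILES,
) -> Pwm:
    """Build a PWM from an IUPAC consensus string using fixed per-letter profiles."""
    cols = []
    for ch in consensus.upper():
        if ch not in profiles:
            raise MotifModelError(f"unknown IUPAC code {ch!r} in consensus {consensus!r}")
        cols.append(list(profiles[ch]))
    probs = np.array(cols, dtype=float).T
    return Pwm(name=name, probs=probs, anchor_offset=anchor_offset, cutoff=cutoff)


# ---------------------------------------------------------------------------
# PWM file format: tab-delimited probabilities, 6 decimal digits.
#
#   #name=<element> anchor_offset=<k> cutoff=<x> [key=value ...]
#   [#citation=<free text>]
#   pos  1  2  ...  L
#   A    p  p  ...  p
#   C    ...
#   G    ...
#   T    ...
#
# Extra key=value tokens on the first line (category=..., window=lo:hi) are
# preserved so a library directory can round-trip bit-exactly.
# ---------------------------------------------------------------------------

_PRECISION = 6


def read_pwm(path) -> tuple[Pwm, dict[str, str]]:
    """Parse a PWM file; returns the Pwm and any extra header metadata."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise MotifModelError(f"{path}: line 1: expected '#name=...' header")
    meta: dict[str, str] = {}
    for tok in lines[0][1:].split():
        if "=" not in tok:
            raise MotifModelError(f"{path}: line 1: malformed token {tok!r}")
        key, _, val = tok.partition("=")
        meta[key] = val
    body = lines[1:]
    while body and body[0].startswith("#"):
        key, _, val = body[0][1:].partition("=")
        meta[key] = val
        body = body[1:]
    if len(body) != 5 or not body[0].startswith("pos"):
        raise MotifModelError(f"{path}: expected a 'pos' header row and 4 nucleotide rows")
    rows: dict[str, list[float]] = {}
    for lineno, line in enumerate(body[1:], start=len(lines) - len(body) + 2):
        fields = line.split("\t")
        nt = fields[0]
        if nt not in NT_INDEX:
            raise MotifModelError(f"{path}: line {lineno}: unexpected row label {nt!r}")
        try:
            rows[nt] = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise MotifModelError(f"{path}: line {lineno}: {exc}") from None
    if set(rows) != set(ALPHABET):
        raise MotifModelError(f"{path}: missing nucleotide rows {set(ALPHABET) - set(rows)}")
    try:
        name = meta.pop("name")
    except KeyError:
        raise MotifModelError(f"{path}: header lacks name=") from None
    anchor_offset = int(meta.pop("anchor_offset", 0))
    cutoff = float(meta.pop("cutoff", 0.0))
    probs = np.array([rows[nt] for nt in ALPHABET], dtype=float)
    pwm = Pwm(name=name, probs=probs, anchor_offset=anchor_offset, cutoff=cutoff)
    return pwm, meta


def write_pwm(pwm: Pwm, path, extra_meta: Mapping[str, str] | None = None) -> None:
    """Write a PWM file that ``read_pwm`` round-trips bit-exactly at 6 digits."""
    extra_meta = dict(extra_meta or {})
    citation = extra_meta.pop("citation", None)
    header = f"#name={pwm.name} anchor_offset={pwm.anchor_offset} cutoff={pwm.cutoff:g}"
    for key in sorted(extra_meta):
        header += f" {key}={extra_meta[key]}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        if citation is not None:
            fh.write(f"#citation={citation}\n")
        fh.write("pos\t" + "\t".join(str(j + 1) for j in range(pwm.length)) + "\n")
        for i, nt in enumerate(ALPHABET):
            fh.write(
                nt + "\t" + "\t".join(f"{p:.{_PRECISION}f}" for p in pwm.probs[i]) + "\n"
            )
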